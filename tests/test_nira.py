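"""Threshold-perturbation intervention simulation."""

import numpy as np
import pytest

import isingnet as ig
from isingnet.nira import PerturbationSpec, perturb_thresholds, run_nira, tau_sd
from isingnet.synthetic import exact_sum_score_stats
from tests.conftest import make_net


class TestPerturbThresholds:
    def test_hand_arithmetic(self):
        # τ = (−1,−2,−3): sample SD = 1; aggravating node 2 by 2 SD → τ₂′ = 0
        net = make_net(np.zeros((3, 3)), [-1.0, -2.0, -3.0])
        out = perturb_thresholds(net, 1, PerturbationSpec(2.0), "aggravate")
        assert out.tau.tolist() == pytest.approx([-1.0, 0.0, -3.0])
        assert np.array_equal(out.W, net.W)

    def test_zero_magnitude_identity(self, triangle_net):
        out = perturb_thresholds(triangle_net, 0, PerturbationSpec(0.0), "aggravate")
        assert out.equals(triangle_net)

    def test_aggravate_then_alleviate_restores(self, triangle_net):
        spec = PerturbationSpec(2.0)
        sd = tau_sd(triangle_net)
        up = perturb_thresholds(triangle_net, 2, spec, "aggravate")
        # compensate manually: the SD is always taken from the *passed*
        # network, so restore with the original SD scale
        down = up.with_tau(up.tau - np.eye(3)[2] * 2 * sd)
        assert np.allclose(down.tau, triangle_net.tau)

    def test_node_by_name(self, triangle_net):
        a = perturb_thresholds(triangle_net, "V2", PerturbationSpec(1.0), "alleviate")
        b = perturb_thresholds(triangle_net, 1, PerturbationSpec(1.0), "alleviate")
        assert a.equals(b)

    def test_single_node_sd_undefined(self):
        net = ig.IsingNetwork(np.zeros((1, 1)), [0.0], ["a"], ["knowledge"])
        with pytest.raises(ValueError, match="single-node"):
            perturb_thresholds(net, 0, PerturbationSpec(), "aggravate")


class TestSimulateSumScores:
    def test_fair_coin_expectation(self):
        p = 32
        net = make_net(np.zeros((p, p)), np.zeros(p))
        scores = ig.simulate_sum_scores(net, 4000, burn_in=50, seed=5)
        se = np.sqrt(p * 0.25 / 4000)
        assert abs(scores.mean() - 16.0) < 3 * se

    def test_matches_exact_expectation(self, triangle_net):
        mean, var = exact_sum_score_stats(triangle_net)
        n = 20000
        scores = ig.simulate_sum_scores(triangle_net, n, burn_in=200, seed=6)
        assert abs(scores.mean() - mean) < 3 * np.sqrt(var / n)

    def test_seed_determinism(self, triangle_net):
        a = ig.simulate_sum_scores(triangle_net, 100, burn_in=100, seed=7)
        b = ig.simulate_sum_scores(triangle_net, 100, burn_in=100, seed=7)
        assert np.array_equal(a, b)

    def test_ci_width_scales_inverse_sqrt_n(self, triangle_net):
        from isingnet.nira import summarize_sum_scores

        widths = []
        for n in (2000, 8000):
            s = ig.simulate_sum_scores(triangle_net, n, burn_in=100, seed=8)
            d = summarize_sum_scores(s)
            widths.append(d["ci_high"] - d["ci_low"])
        ratio = widths[0] / widths[1]
        assert ratio == pytest.approx(2.0, rel=0.15)


def positive_toy_net():
    W = np.zeros((5, 5))
    for i, j, w in [(0, 1, 0.8), (1, 2, 0.6), (2, 3, 0.9), (0, 4, 0.5)]:
        W[i, j] = W[j, i] = w
    return make_net(W, [-1.0, -0.4, -1.6, -0.2, -0.9],
                    communities=["a", "a", "a", "b", "b"])


class TestRunNira:
    def test_monotone_under_nonnegative_weights_exact(self):
        """With W ≥ 0 the Ising measure is stochastically monotone in each
        threshold: aggravation can only raise, alleviation only lower, the
        exact expected sum score (checked by enumeration)."""
        net = positive_toy_net()
        base, _ = exact_sum_score_stats(net)
        spec = PerturbationSpec(2.0)
        for node in range(net.p):
            up, _ = exact_sum_score_stats(perturb_thresholds(net, node, spec, "aggravate"))
            down, _ = exact_sum_score_stats(perturb_thresholds(net, node, spec, "alleviate"))
            assert up >= base - 1e-12
            assert down <= base + 1e-12

    def test_zero_magnitude_cis_overlap_baseline(self):
        net = positive_toy_net()
        res = run_nira(net, PerturbationSpec(0.0), n_persons=1500, burn_in=100, seed=9)
        b = res.baseline
        for _, row in res.table[res.table["direction"] != "baseline"].iterrows():
            assert row["ci_low"] <= b["ci_high"] and b["ci_low"] <= row["ci_high"]

    def test_table_shape_and_ranks(self):
        net = positive_toy_net()
        res = run_nira(net, n_persons=800, burn_in=100, seed=10)
        assert len(res.table) == 1 + 2 * net.p
        assert (res.table["direction"] == "baseline").sum() == 1
        for d in ("aggravate", "alleviate"):
            ranks = sorted(res.table.loc[res.table["direction"] == d, "rank"])
            assert ranks == list(range(1, net.p + 1))
        # rank 1 = max mean when aggravating, min mean when alleviating
        agg = res.ranked("aggravate")
        assert agg["mean"].is_monotonic_decreasing
        alv = res.ranked("alleviate")
        assert alv["mean"].is_monotonic_increasing

    def test_ci_contains_mean(self):
        net = positive_toy_net()
        res = run_nira(net, n_persons=500, burn_in=100, seed=11)
        t = res.table
        assert (t["ci_low"] <= t["mean"]).all() and (t["mean"] <= t["ci_high"]).all()

    def test_bridge_node_outranks_isolated_node_of_equal_threshold(self):
        """A well-connected node drags the rest of the network with it, so
        aggravating it moves the exact expected sum score more than
        aggravating an isolated node with the same threshold."""
        W = np.zeros((6, 6))
        for i, j in [(0, 1), (0, 2), (0, 3), (0, 4)]:
            W[i, j] = W[j, i] = 0.9
        # node 5 isolated, same threshold as hub node 0
        net = make_net(W, [-1.2, -0.8, -0.8, -0.8, -0.8, -1.2],
                       communities=["a"] * 3 + ["b"] * 3)
        base, _ = exact_sum_score_stats(net)
        spec = PerturbationSpec(2.0)
        hub, _ = exact_sum_score_stats(perturb_thresholds(net, 0, spec, "aggravate"))
        iso, _ = exact_sum_score_stats(perturb_thresholds(net, 5, spec, "aggravate"))
        assert hub - base > iso - base

    def test_seed_determinism(self):
        net = positive_toy_net()
        a = run_nira(net, n_persons=300, burn_in=100, seed=12).table
        b = run_nira(net, n_persons=300, burn_in=100, seed=12).table
        assert a.equals(b)
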