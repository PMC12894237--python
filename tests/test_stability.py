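"""Case-dropping bootstrap, CS coefficient, and edge bootstrap."""

import numpy as np
import pandas as pd
import pytest

import isingnet as ig
from isingnet.elasso import EstimationConfig
from isingnet.stability import StabilityResult, case_drop_bootstrap, cs_coefficient
from tests.conftest import chain_network

FAST = EstimationConfig(n_lambda=30, lambda_min_ratio=0.05, tol=1e-5)


def make_result(rows, grid, reps):
    return StabilityResult(pd.DataFrame(rows), tuple(grid), reps, {}, {}, 0)


class TestCsCoefficient:
    def test_all_perfect_correlations_give_max_grid(self):
        grid = (0.1, 0.3, 0.5)
        rows = [
            {"proportion": q, "replicate": r, "metric": "strength", "correlation": 1.0}
            for q in grid for r in range(20)
        ]
        cs = cs_coefficient(make_result(rows, grid, 20))
        assert cs["strength"] == 0.5

    def test_all_zero_correlations_give_zero(self):
        grid = (0.1, 0.3)
        rows = [
            {"proportion": q, "replicate": r, "metric": "strength", "correlation": 0.0}
            for q in grid for r in range(20)
        ]
        assert cs_coefficient(make_result(rows, grid, 20))["strength"] == 0.0

    def test_boundary_fixture_pass_rate(self):
        """Exactly 95% of replicates ≥ 0.7 at q=0.5 but only 90% at 0.55
        → CS = 0.5."""
        grid = (0.5, 0.55)
        rows = []
        for r in range(100):
            rows.append({"proportion": 0.5, "replicate": r, "metric": "strength",
                         "correlation": 0.9 if r < 95 else 0.1})
            rows.append({"proportion": 0.55, "replicate": r, "metric": "strength",
                         "correlation": 0.9 if r < 90 else 0.1})
        assert cs_coefficient(make_result(rows, grid, 100))["strength"] == 0.5

    def test_monotone_in_threshold_arguments(self):
        rng = np.random.default_rng(3)
        grid = tuple(np.round(np.arange(0.1, 0.71, 0.1), 2))
        rows = [
            {"proportion": q, "replicate": r, "metric": "m",
             "correlation": rng.uniform(0.3, 1.0)}
            for q in grid for r in range(40)
        ]
        res = make_result(rows, grid, 40)
        for thr_lo, thr_hi in [(0.5, 0.7), (0.7, 0.9)]:
            assert cs_coefficient(res, thr_hi)["m"] <= cs_coefficient(res, thr_lo)["m"]
        for p_lo, p_hi in [(0.8, 0.95), (0.9, 0.99)]:
            assert (cs_coefficient(res, 0.7, p_hi)["m"]
                    <= cs_coefficient(res, 0.7, p_lo)["m"])


class TestCaseDropBootstrap:
    def test_dropping_zero_rows_gives_correlation_one(self):
        net = chain_network(p=4, beta=1.5, tau=-0.5)
        X = ig.gibbs_sample(net, ig.SimulationConfig(100, 200, 8))
        # q so small the kept count rounds back up to n
        res = case_drop_bootstrap(X, grid=(0.001,), reps=2, cfg=FAST, seed=1)
        assert np.allclose(res.correlations["correlation"], 1.0)

    def test_same_seed_identical(self):
        net = chain_network(p=4, beta=1.5, tau=-0.5)
        X = ig.gibbs_sample(net, ig.SimulationConfig(400, 200, 8))
        a = case_drop_bootstrap(X, grid=(0.3,), reps=3, cfg=FAST, seed=5)
        b = case_drop_bootstrap(X, grid=(0.3,), reps=3, cfg=FAST, seed=5)
        pd.testing.assert_frame_equal(a.correlations, b.correlations)

    def test_perfectly_stable_estimator_reaches_max_grid(self):
        """With a deterministic data-independent metric, every replicate
        correlates perfectly and CS hits the top of the grid."""
        X = ig.BinaryResponseMatrix(
            np.random.default_rng(0).integers(0, 2, (200, 3)), ("a", "b", "c")
        )
        res = case_drop_bootstrap(
            X, grid=(0.25, 0.5, 0.75), reps=10, seed=2,
            estimator=lambda values: None,
            metric_fns={"m": lambda net: np.array([1.0, 2.0, 3.0])},
        )
        assert cs_coefficient(res)["m"] == 0.75

    def test_pure_noise_metric_gives_zero_cs(self):
        rng = np.random.default_rng(11)
        X = ig.BinaryResponseMatrix(rng.integers(0, 2, (200, 8)), tuple("abcdefgh"))
        noise = np.random.default_rng(99)
        res = case_drop_bootstrap(
            X, grid=(0.1, 0.5), reps=30, seed=3,
            estimator=lambda values: None,
            metric_fns={"m": lambda net: noise.normal(size=8)},
        )
        assert cs_coefficient(res)["m"] == 0.0

    def test_constant_metric_flagged_not_crashing(self):
        """An estimator whose metric is constant across nodes yields
        undefined correlations; they surface as NaN and CS degrades to 0."""
        X = ig.BinaryResponseMatrix(
            np.random.default_rng(1).integers(0, 2, (150, 3)), ("a", "b", "c")
        )
        res = case_drop_bootstrap(
            X, grid=(0.2,), reps=4, seed=4,
            estimator=lambda values: None,
            metric_fns={"m": lambda net: np.ones(3)},
        )
        assert res.correlations["correlation"].isna().all()
        assert cs_coefficient(res)["m"] == 0.0

    def test_degenerate_subsample_skipped_and_counted(self):
        # one item endorsed by a single respondent: most 50%-drop
        # subsamples lose the category entirely
        v = np.random.default_rng(0).integers(0, 2, (40, 3))
        v[:, 0] = 0
        v[0, 0] = 1
        X = ig.BinaryResponseMatrix(v, ("a", "b", "c"))
        with pytest.warns(UserWarning, match="skipped"):
            res = case_drop_bootstrap(X, grid=(0.5,), reps=20, cfg=FAST, seed=6)
        assert res.n_skipped[0.5] > 0
        n_metrics = res.correlations["metric"].nunique() if len(res.correlations) else 1
        n_kept = len(res.correlations) // n_metrics
        assert n_kept + res.n_skipped[0.5] == 20


class TestEdgeBootstrap:
    def test_constant_estimator_degenerate_cis(self, triangle_net):
        X = ig.BinaryResponseMatrix(
            np.random.default_rng(2).integers(0, 2, (100, 3)), triangle_net.item_ids
        )
        res = ig.edge_bootstrap(X, reps=10, seed=7, estimator=lambda v: triangle_net)
        t = res.table.set_index(["source", "target"])
        # present edge: CI collapses on its weight; absent edge: [0, 0]
        assert t.loc[("V1", "V2"), "ci_low"] == pytest.approx(0.5)
        assert t.loc[("V1", "V2"), "ci_high"] == pytest.approx(0.5)
        assert t.loc[("V2", "V3"), "ci_low"] == 0 == t.loc[("V2", "V3"), "ci_high"]

    def test_planted_strong_edge_ci_excludes_zero(self):
        net = chain_network(p=4, beta=1.5, tau=-0.5)
        X = ig.gibbs_sample(net, ig.SimulationConfig(2000, 300, 13))
        res = ig.edge_bootstrap(X, reps=40, cfg=FAST, seed=8)
        t = res.table.set_index(["source", "target"])
        assert t.loc[("V1", "V2"), "ci_low"] > 0

    def test_seed_determinism(self):
        net = chain_network(p=4, beta=1.2, tau=-0.5)
        X = ig.gibbs_sample(net, ig.SimulationConfig(500, 200, 14))
        a = ig.edge_bootstrap(X, reps=5, cfg=FAST, seed=9)
        b = ig.edge_bootstrap(X, reps=5, cfg=FAST, seed=9)
        pd.testing.assert_frame_equal(a.table, b.table)
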