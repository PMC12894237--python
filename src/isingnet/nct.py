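"""Permutation-based two-group network comparison.

Networks are estimated separately per group; the test statistics are the
absolute difference in global strength (Σ_{i<j} |w_ij|), the maximum
absolute edge difference (network-structure test), per-edge absolute
differences, and per-node expected-influence differences.  The null
distribution comes from re-assigning respondents to pseudo-groups of the
original sizes and re-running the full estimation on both, so the
reference distribution reflects estimation noise, not just weight
resampling.  p-values use the add-one permutation estimator
p = (#{perm ≥ obs} + 1)/(n_perm + 1), and per-edge / per-node families
get a Holm correction by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .centrality import expected_influence
from .codebook import BinaryResponseMatrix
from .elasso import EstimationConfig, estimate_network
from .network import IsingNetwork

__all__ = ["NctResult", "global_strength", "nct_test"]


def global_strength(net: IsingNetwork) -> float:
    """Sum of absolute upper-triangle edge weights."""
    return float(np.abs(np.triu(net.W, 1)).sum())


@dataclass(frozen=True)
class NctResult:
    global_strength_a: float
    global_strength_b: float
    global_strength_diff: float
    p_global: float
    max_edge_diff: float
    p_structure: float
    edge_tests: pd.DataFrame  # source, target, diff, p, p_holm
    node_tests: pd.DataFrame  # item_id, ei_diff, p, p_holm
    n_perm: int
    n_redrawn: int
    seed: int


def _degenerate(values: np.ndarray) -> bool:
    m = values.mean(axis=0)
    return bool(np.any((m == 0) | (m == 1)))


def nct_test(
    X_A: BinaryResponseMatrix,
    X_B: BinaryResponseMatrix,
    n_perm: int = 1000,
    cfg: EstimationConfig = EstimationConfig(),
    seed: int = 0,
    correction: str = "holm",
    max_redraw_factor: int = 10,
) -> NctResult:
    """Permutation test of network invariance between two groups.

    Group sizes are preserved in every permutation; a permutation whose
    pseudo-group loses a response category in some column is redrawn
    (counted, capped at ``max_redraw_factor``·``n_perm`` total redraws).
    """
    if X_A.item_ids != X_B.item_ids:
        raise ValueError("both groups must share the same item columns")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    item_ids = X_A.item_ids
    p = len(item_ids)
    iu = np.triu_indices(p, 1)

    def fit(values: np.ndarray) -> IsingNetwork:
        return estimate_network(BinaryResponseMatrix(values, item_ids), cfg)

    net_a, net_b = fit(X_A.values), fit(X_B.values)
    s_a, s_b = global_strength(net_a), global_strength(net_b)
    obs_global = abs(s_a - s_b)
    obs_edges = np.abs(net_a.W[iu] - net_b.W[iu])
    obs_structure = float(obs_edges.max()) if obs_edges.size else 0.0
    obs_nodes = np.abs(expected_influence(net_a) - expected_influence(net_b))

    pooled = np.vstack([X_A.values, X_B.values])
    # canonical (lexicographic) row order makes the permutation null — and
    # hence the p-values — exactly invariant to swapping the group labels
    if p <= 63:
        keys = pooled.astype(np.uint64) @ (np.uint64(1) << np.arange(p, dtype=np.uint64))
        pooled = pooled[np.argsort(keys, kind="stable")]
    # pseudo-group sizes preserve the observed sizes; always carving the
    # smaller group first keeps the split orientation-free too
    n_small, n_total = min(X_A.n, X_B.n), X_A.n + X_B.n
    rng = np.random.default_rng(seed)

    ge_global = 0
    ge_structure = 0
    ge_edges = np.zeros(obs_edges.shape[0], dtype=int)
    ge_nodes = np.zeros(p, dtype=int)
    n_redrawn = 0
    max_redraws = max_redraw_factor * n_perm
    done = 0
    while done < n_perm:
        perm = rng.permutation(n_total)
        va, vb = pooled[perm[:n_small]], pooled[perm[n_small:]]
        if _degenerate(va) or _degenerate(vb):
            n_redrawn += 1
            if n_redrawn > max_redraws:
                raise RuntimeError(
                    "too many degenerate permutations; groups too small for "
                    "these item marginals"
                )
            continue
        pa, pb = fit(va), fit(vb)
        diff_edges = np.abs(pa.W[iu] - pb.W[iu])
        if abs(global_strength(pa) - global_strength(pb)) >= obs_global:
            ge_global += 1
        if (diff_edges.max() if diff_edges.size else 0.0) >= obs_structure:
            ge_structure += 1
        ge_edges += diff_edges >= obs_edges
        ge_nodes += np.abs(expected_influence(pa) - expected_influence(pb)) >= obs_nodes
        done += 1

    def pval(count: np.ndarray | int) -> np.ndarray | float:
        return (np.asarray(count) + 1.0) / (n_perm + 1.0)

    p_edges = np.atleast_1d(pval(ge_edges))
    p_nodes = np.atleast_1d(pval(ge_nodes))
    if correction == "holm":
        edge_adj = multipletests(p_edges, method="holm")[1] if p_edges.size else p_edges
        node_adj = multipletests(p_nodes, method="holm")[1]
    elif correction == "none":
        edge_adj, node_adj = p_edges, p_nodes
    else:
        raise ValueError(f"unknown correction {correction!r}")

    edge_tests = pd.DataFrame(
        {
            "source": [item_ids[i] for i in iu[0]],
            "target": [item_ids[j] for j in iu[1]],
            "diff": obs_edges,
            "p": p_edges,
            "p_adj": edge_adj,
        }
    )
    node_tests = pd.DataFrame(
        {"item_id": list(item_ids), "ei_diff": obs_nodes, "p": p_nodes, "p_adj": node_adj}
    )
    if n_redrawn:
        warnings.warn(f"{n_redrawn} degenerate permutation(s) redrawn", stacklevel=2)
    return NctResult(
        s_a, s_b, obs_global, float(pval(ge_global)),
        obs_structure, float(pval(ge_structure)),
        edge_tests, node_tests, n_perm, n_redrawn, seed,
    )
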