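"""Estimation robustness: case-dropping bootstrap and edge-weight bootstrap.

The correlation-stability (CS) coefficient summarizes how many cases can
be dropped while the centrality ordering survives: it is the largest
drop proportion q at which, in at least ``prob`` (default 95%) of
replicates, the subsample centrality vector correlates at least
``cor_threshold`` (default 0.7) with the full-sample vector.  Values
above 0.25 are conventionally read as acceptable stability and above 0.5
as good.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .centrality import bridge_expected_influence, expected_influence, strength
from .codebook import BinaryResponseMatrix
from .elasso import EstimationConfig, estimate_network
from .network import IsingNetwork

__all__ = [
    "DEFAULT_DROP_GRID",
    "StabilityResult",
    "case_drop_bootstrap",
    "cs_coefficient",
    "edge_bootstrap",
]

DEFAULT_DROP_GRID: tuple[float, ...] = tuple(np.round(np.arange(0.10, 0.751, 0.05), 2))

DEFAULT_METRICS: dict[str, Callable[[IsingNetwork], np.ndarray]] = {
    "strength": strength,
    "expected_influence": expected_influence,
    "bridge_expected_influence": bridge_expected_influence,
}


@dataclass(frozen=True)
class StabilityResult:
    """Long-format replicate correlations plus bookkeeping.

    ``correlations`` columns: proportion, replicate, metric, correlation
    (NaN when the correlation was undefined, e.g. a constant vector).
    ``n_skipped`` counts replicates dropped because the subsample lost a
    response category in some column.
    """

    correlations: pd.DataFrame
    grid: tuple[float, ...]
    reps: int
    n_skipped: dict
    full_metrics: dict
    seed: int


def _default_estimator(X: BinaryResponseMatrix, cfg: EstimationConfig):
    def est(values: np.ndarray) -> IsingNetwork:
        return estimate_network(
            BinaryResponseMatrix(values, X.item_ids), cfg,
            communities=_communities_of(X),
        )
    return est


def _communities_of(X: BinaryResponseMatrix):
    from .elasso import _default_communities

    return _default_communities(X.item_ids)


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def case_drop_bootstrap(
    X: BinaryResponseMatrix,
    grid: Sequence[float] = DEFAULT_DROP_GRID,
    reps: int = 500,
    cfg: EstimationConfig = EstimationConfig(),
    seed: int = 0,
    metric_fns: Mapping[str, Callable[[IsingNetwork], np.ndarray]] | None = None,
    estimator: Callable[[np.ndarray], IsingNetwork] | None = None,
) -> StabilityResult:
    """Case-dropping bootstrap of centrality stability.

    For each drop proportion q and replicate, ⌈(1−q)·n⌉ rows are drawn
    without replacement, the network re-estimated, and each metric
    vector correlated (Pearson, nodes as units) with its full-sample
    counterpart.  Replicate randomness uses per-(q, replicate) seed
    substreams, so results do not depend on evaluation order.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    grid = tuple(float(q) for q in grid)
    if any(not 0 < q < 1 for q in grid):
        raise ValueError("drop proportions must lie in (0, 1)")
    est = estimator if estimator is not None else _default_estimator(X, cfg)

    full_net = est(X.values)
    if metric_fns is None:
        metric_fns = dict(DEFAULT_METRICS)
        try:
            bridge_expected_influence(full_net)
        except (ValueError, AttributeError, TypeError):
            # single-community (or custom-estimator) networks have no
            # bridge metric; stability then covers strength and EI
            metric_fns.pop("bridge_expected_influence")
    else:
        metric_fns = dict(metric_fns)
    full_metrics = {m: np.asarray(fn(full_net), dtype=float) for m, fn in metric_fns.items()}

    children = np.random.SeedSequence(seed).spawn(len(grid) * reps)
    rows = []
    n_skipped = {q: 0 for q in grid}
    for qi, q in enumerate(grid):
        keep = int(np.ceil((1.0 - q) * X.n))
        for r in range(reps):
            rng = np.random.default_rng(children[qi * reps + r])
            idx = rng.choice(X.n, size=keep, replace=False)
            sub = X.values[idx]
            means = sub.mean(axis=0)
            if np.any((means == 0) | (means == 1)):
                n_skipped[q] += 1
                continue
            net = est(sub)
            for m, fn in metric_fns.items():
                rows.append(
                    {
                        "proportion": q,
                        "replicate": r,
                        "metric": m,
                        "correlation": _safe_corr(np.asarray(fn(net), float), full_metrics[m]),
                    }
                )
    total_skipped = sum(n_skipped.values())
    if total_skipped:
        warnings.warn(
            f"{total_skipped} replicate(s) skipped: subsample lost a response "
            "category in some column", stacklevel=2,
        )
    corr = pd.DataFrame(rows, columns=["proportion", "replicate", "metric", "correlation"])
    return StabilityResult(corr, grid, reps, n_skipped, full_metrics, seed)


def cs_coefficient(
    result: StabilityResult, cor_threshold: float = 0.7, prob: float = 0.95
) -> dict[str, float]:
    """CS coefficient per metric: the largest drop proportion at which at
    least ``prob`` of (non-skipped) replicates correlate ≥ ``cor_threshold``
    with the full sample; 0 if no grid point qualifies.  Undefined
    (NaN) correlations count as failures.
    """
    out = {}
    df = result.correlations
    for m in df["metric"].unique() if len(df) else []:
        sub = df[df["metric"] == m]
        cs = 0.0
        for q in result.grid:
            at_q = sub[sub["proportion"] == q]["correlation"]
            if len(at_q) == 0:
                continue
            pass_frac = float((at_q >= cor_threshold).sum()) / len(at_q)
            if pass_frac >= prob:
                cs = q
        out[m] = cs
    return out


@dataclass(frozen=True)
class EdgeBootstrapResult:
    table: pd.DataFrame  # source, target, observed, boot_mean, ci_low, ci_high
    reps: int
    n_skipped: int
    seed: int


def edge_bootstrap(
    X: BinaryResponseMatrix,
    reps: int = 500,
    cfg: EstimationConfig = EstimationConfig(),
    seed: int = 0,
    estimator: Callable[[np.ndarray], IsingNetwork] | None = None,
    ci: tuple[float, float] = (2.5, 97.5),
) -> EdgeBootstrapResult:
    """Nonparametric bootstrap of edge weights (resample n rows with
    replacement, re-estimate, percentile CIs per edge over all node
    pairs).  Degenerate resamples are skipped and counted.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    est = estimator if estimator is not None else _default_estimator(X, cfg)
    full_net = est(X.values)
    p = full_net.p
    iu = np.triu_indices(p, 1)
    children = np.random.SeedSequence(seed).spawn(reps)
    draws = []
    n_skipped = 0
    for r in range(reps):
        rng = np.random.default_rng(children[r])
        idx = rng.integers(0, X.n, size=X.n)
        sub = X.values[idx]
        means = sub.mean(axis=0)
        if np.any((means == 0) | (means == 1)):
            n_skipped += 1
            continue
        draws.append(est(sub).W[iu])
    if n_skipped:
        warnings.warn(f"{n_skipped} bootstrap resample(s) skipped as degenerate",
                      stacklevel=2)
    if not draws:
        raise RuntimeError("every bootstrap resample was degenerate")
    D = np.vstack(draws)
    lo, hi = np.percentile(D, ci, axis=0)
    table = pd.DataFrame(
        {
            "source": [full_net.item_ids[i] for i in iu[0]],
            "target": [full_net.item_ids[j] for j in iu[1]],
            "observed": full_net.W[iu],
            "boot_mean": D.mean(axis=0),
            "ci_low": lo,
            "ci_high": hi,
        }
    )
    return EdgeBootstrapResult(table, reps, n_skipped, seed)
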