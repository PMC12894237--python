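"""eLasso network estimation: nodewise ℓ1-logistic regression with EBIC.

Each item is regressed on all other items with an ℓ1 penalty along a
geometric λ path; the Extended Bayesian Information Criterion

    EBIC(λ) = −2ℓ + k·log n + 2γ·k·log(p−1)

(k = number of nonzero neighbour coefficients, γ default 0.25) selects
the active neighbourhood per node.  The p nodewise fits are then
symmetrized: under the AND rule an edge survives only if both incident
regressions select it, with weight equal to the mean of the two
coefficients; under the OR rule one selection suffices.  Intercepts of
the selected nodewise models become the node thresholds.  Predictors are
the raw {0,1} columns, unstandardized, so threshold magnitudes are
interpretable on the endorsement-probability scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._kernels import lasso_logistic_path, refit_mle
from .codebook import BinaryResponseMatrix
from .network import IsingNetwork

__all__ = ["EstimationConfig", "NodewiseFit", "ebic", "fit_node", "estimate_network"]

# coefficient magnitude beyond which a fit is treated as quasi-separated
# and the λ path truncated (|β|=15 ⇒ odds ratio > 3·10⁶ — never a real edge)
COEF_BOUND = 15.0

# selected coefficients below this magnitude are numerical zeros, not edges
_ZERO_TOL = 1e-7


@dataclass(frozen=True)
class EstimationConfig:
    """Settings for nodewise estimation.

    ``refit`` selects the relaxed variant: the EBIC of each λ-path point
    is evaluated at the unpenalized maximum-likelihood refit of its
    active set (and the refit coefficients are reported), so model
    selection is not distorted by ℓ1 shrinkage of the log-likelihood.
    With ``refit=False`` both selection and coefficients use the
    penalized path fits.  Supports larger than ``refit_k_max`` keep
    their penalized values (their EBIC is dominated by the k·log n
    penalty regardless).
    """

    gamma: float = 0.25
    n_lambda: int = 100
    lambda_min_ratio: float = 0.01
    rule: str = "AND"
    refit: bool = True
    refit_k_max: int = 16
    max_outer: int = 40
    max_inner: int = 40
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.n_lambda < 2:
            raise ValueError("n_lambda must be >= 2")
        if not 0 < self.lambda_min_ratio < 1:
            raise ValueError("lambda_min_ratio must be in (0, 1)")
        if self.rule not in ("AND", "OR"):
            raise ValueError("rule must be 'AND' or 'OR'")


@dataclass(frozen=True)
class NodewiseFit:
    """Path of ℓ1-logistic fits for one node and its EBIC selection."""

    node: int
    lambdas: np.ndarray
    coefs: np.ndarray  # n_valid × (p−1), neighbour coefficients
    intercepts: np.ndarray
    logliks: np.ndarray
    ebics: np.ndarray
    selected: int
    truncated: bool

    @property
    def selected_coefs(self) -> np.ndarray:
        return self.coefs[self.selected]

    @property
    def selected_intercept(self) -> float:
        return float(self.intercepts[self.selected])

    @property
    def selected_k(self) -> int:
        return int(np.count_nonzero(self.coefs[self.selected]))


def ebic(loglik: float, k: int, n: int, p: int, gamma: float) -> float:
    """Extended BIC of a nodewise logistic model with k active neighbours.

    With γ = 0 this reduces to the ordinary BIC; larger γ penalizes the
    log(p−1)-sized candidate-neighbour space and yields sparser graphs.
    """
    if n < 1 or p < 2 or k < 0:
        raise ValueError("require n >= 1, p >= 2, k >= 0")
    return -2.0 * loglik + k * np.log(n) + 2.0 * gamma * k * np.log(p - 1)


def unique_rows(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse a {0,1} matrix to its distinct rows and multiplicities.

    Exact sufficient-statistics reduction for binary data: every
    nodewise regression on the collapsed rows (weighted by counts)
    equals the regression on the full matrix.  Rows are bit-packed for
    speed when p ≤ 63.
    """
    v = np.asarray(values)
    n, p = v.shape
    if p <= 63:
        keys = v.astype(np.uint64) @ (np.uint64(1) << np.arange(p, dtype=np.uint64))
        uniq, first_idx, counts = np.unique(keys, return_index=True, return_counts=True)
        return v[first_idx].astype(np.float64), counts.astype(np.float64)
    uniq, counts = np.unique(v, axis=0, return_counts=True)
    return uniq.astype(np.float64), counts.astype(np.float64)


def _lambda_path(
    others: np.ndarray, y: np.ndarray, counts: np.ndarray, n: int, cfg: EstimationConfig
) -> np.ndarray:
    # λ_max: smallest penalty that zeroes every coefficient at the
    # intercept-only solution (KKT condition of the ℓ1 problem)
    ybar = float(counts @ y) / n
    lam_max = np.max(np.abs(others.T @ (counts * (y - ybar)))) / n
    if lam_max <= 0:
        lam_max = 1e-3
    # nudge the anchor above the exact KKT bound so the first path point
    # is the empty model despite floating-point wobble in the gradient
    lam_max *= 1.0 + 1e-8
    return np.geomspace(lam_max, lam_max * cfg.lambda_min_ratio, cfg.n_lambda)


def fit_node(
    X, i: int, cfg: EstimationConfig = EstimationConfig(), _collapsed=None
) -> NodewiseFit:
    """Fit node ``i``'s penalized neighbourhood regression along the λ path.

    ``X`` is a BinaryResponseMatrix or {0,1} array.  Ties in EBIC break
    toward the larger λ (sparser model).  A path truncated by the
    quasi-separation guard triggers a warning but still returns the
    valid prefix.
    """
    values = X.values if isinstance(X, BinaryResponseMatrix) else np.asarray(X)
    n, p = values.shape
    if values[:, i].min() == values[:, i].max():
        raise ValueError(f"column {i} has a single response value; cannot fit")
    rows, counts = unique_rows(values) if _collapsed is None else _collapsed
    y = np.ascontiguousarray(rows[:, i])
    others = np.ascontiguousarray(np.delete(rows, i, axis=1))
    lambdas = _lambda_path(others, y, counts, n, cfg)
    coefs, intercepts, logliks, n_valid = lasso_logistic_path(
        others, y, counts, n, lambdas, cfg.max_outer, cfg.max_inner, cfg.tol,
        COEF_BOUND,
    )
    truncated = n_valid < cfg.n_lambda
    if truncated:
        warnings.warn(
            f"node {i}: λ path truncated at {n_valid}/{cfg.n_lambda} "
            "(coefficient magnitude guard; data may be quasi-separated)",
            stacklevel=2,
        )
        if n_valid == 0:
            raise ValueError(f"node {i}: no valid path point before separation guard")
    lambdas = lambdas[:n_valid]
    coefs = coefs[:n_valid]
    coefs[np.abs(coefs) < _ZERO_TOL] = 0.0
    intercepts = intercepts[:n_valid]
    logliks = logliks[:n_valid]
    if cfg.refit:
        # relaxed selection: one unpenalized MLE per distinct active set,
        # shared by every path point with that support
        cache: dict[tuple, tuple] = {}
        for l in range(len(lambdas)):
            support = tuple(np.nonzero(coefs[l])[0])
            if len(support) > cfg.refit_k_max:
                continue
            if support not in cache:
                cache[support] = refit_mle(
                    others, y, counts, n,
                    np.asarray(support, dtype=np.int64), 60, 1e-9, COEF_BOUND,
                )
            beta_s, b0, ll, _conv = cache[support]
            coefs[l] = 0.0
            coefs[l, list(support)] = beta_s
            intercepts[l] = b0
            logliks[l] = ll
    ks = np.count_nonzero(coefs, axis=1)
    # vectorized ebic(); kept in sync with the scalar definition above
    ebics = -2.0 * logliks + ks * (np.log(n) + 2.0 * cfg.gamma * np.log(p - 1))
    selected = int(np.argmin(ebics))  # argmin takes the first (largest-λ) tie
    return NodewiseFit(i, lambdas, coefs, intercepts, logliks, ebics, selected, truncated)


def estimate_network(
    X, cfg: EstimationConfig = EstimationConfig(), communities=None
) -> IsingNetwork:
    """Estimate the Ising network from a binary response matrix.

    Runs :func:`fit_node` for every column and symmetrizes the selected
    coefficient matrix with the configured AND/OR rule.  Thresholds are
    the intercepts of each node's own selected model.
    """
    if isinstance(X, BinaryResponseMatrix):
        X.require_both_classes()
        values = X.values
        item_ids = X.item_ids
    else:
        values = np.asarray(X)
        item_ids = tuple(f"V{j + 1}" for j in range(values.shape[1]))
        means = values.mean(axis=0)
        if np.any((means == 0) | (means == 1)):
            raise ValueError("all columns must contain both response values")
    n, p = values.shape
    collapsed = unique_rows(values)
    B = np.zeros((p, p))  # B[i, j]: coefficient of item j in node i's model
    tau = np.zeros(p)
    for i in range(p):
        f = fit_node(values, i, cfg, _collapsed=collapsed)
        row = f.selected_coefs
        B[i, :i] = row[:i]
        B[i, i + 1:] = row[i:]
        tau[i] = f.selected_intercept
    both = (B != 0) & (B.T != 0)
    either = (B != 0) | (B.T != 0)
    mean_b = (B + B.T) / 2.0
    if cfg.rule == "AND":
        W = np.where(both, mean_b, 0.0)
    else:  # OR: mean of the nonzero entries
        W = np.where(both, mean_b, np.where(either, B + B.T, 0.0))
    np.fill_diagonal(W, 0.0)
    if communities is None:
        communities = _default_communities(item_ids)
    return IsingNetwork(W, tau, item_ids, communities)


def _default_communities(item_ids) -> tuple[str, ...]:
    """Infer community labels from conventional item-id prefixes."""
    out = []
    for nid in item_ids:
        if nid.lower().startswith(("stigma", "pdd")):
            out.append("stigma")
        else:
            out.append("knowledge")
    return tuple(out)
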