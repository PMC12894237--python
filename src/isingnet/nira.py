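"""Threshold-perturbation intervention simulation (NIRA-style).

For each node in turn, its threshold is shifted by ±``magnitude``
standard deviations of the full estimated threshold vector — raising a
threshold makes the item easier to endorse ("aggravating" when items
code deficits and stigma endorsement), lowering it models a successful
intervention ("alleviating").  Respondents are then Gibbs-sampled from
each altered model and the per-person sum score S = Σ_i x_i summarized
(mean, 95% CI).  Nodes are ranked by the resulting mean sum score:
descending for aggravation (which node inflates the network most when
entrenched) and ascending for alleviation (which node deflates it most
when corrected).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .network import IsingNetwork
from .synthetic import SimulationConfig, gibbs_sample

__all__ = [
    "PerturbationSpec",
    "NiraResult",
    "perturb_thresholds",
    "simulate_sum_scores",
    "run_nira",
]

DIRECTIONS = ("aggravate", "alleviate")
_SIGN = {"aggravate": +1.0, "alleviate": -1.0}


@dataclass(frozen=True)
class PerturbationSpec:
    """Size of the threshold shift, in SDs of the threshold vector.

    The SD is the sample standard deviation of all p estimated
    thresholds (not a per-node standard error).
    """

    magnitude: float = 2.0

    def __post_init__(self) -> None:
        if self.magnitude < 0:
            raise ValueError("magnitude must be >= 0")


@dataclass(frozen=True)
class NiraResult:
    """Per (node, direction) sum-score summaries plus the baseline row.

    ``table`` columns: item_id, direction, mean, ci_low, ci_high,
    n_persons, rank (rank 1 = largest mean under aggravation, smallest
    under alleviation; baseline has no rank).
    """

    table: pd.DataFrame
    magnitude: float
    tau_sd: float
    seed: int

    def ranked(self, direction: str) -> pd.DataFrame:
        sub = self.table[self.table["direction"] == direction]
        return sub.sort_values("rank").reset_index(drop=True)

    @property
    def baseline(self) -> pd.Series:
        return self.table[self.table["direction"] == "baseline"].iloc[0]


def tau_sd(net: IsingNetwork) -> float:
    if net.p < 2:
        raise ValueError("threshold SD undefined for a single-node network")
    return float(np.std(net.tau, ddof=1))


def perturb_thresholds(
    net: IsingNetwork, node: int | str, spec: PerturbationSpec, direction: str
) -> IsingNetwork:
    """Shift one node's threshold by ±magnitude·SD(τ); W untouched."""
    if direction not in _SIGN:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    if isinstance(node, str):
        node = net.item_ids.index(node)
    if not 0 <= node < net.p:
        raise ValueError(f"node index {node} out of range")
    tau = net.tau.copy()
    tau[node] += _SIGN[direction] * spec.magnitude * tau_sd(net)
    return net.with_tau(tau)


def summarize_sum_scores(scores: np.ndarray) -> dict:
    """Mean and normal-approximation 95% CI of a sum-score sample."""
    n = scores.shape[0]
    if n < 2:
        raise ValueError("need at least two simulated persons")
    mean = float(scores.mean())
    half = 1.96 * float(scores.std(ddof=1)) / np.sqrt(n)
    return {"mean": mean, "ci_low": mean - half, "ci_high": mean + half, "n_persons": n}


def simulate_sum_scores(
    net: IsingNetwork, n_persons: int, burn_in: int = 1000, seed: int = 0
) -> np.ndarray:
    """Gibbs-sample ``n_persons`` independent respondents; return their
    sum scores (integers in [0, p])."""
    X = gibbs_sample(net, SimulationConfig(n_persons, burn_in, seed))
    return X.values.sum(axis=1).astype(float)


def run_nira(
    net: IsingNetwork,
    spec: PerturbationSpec = PerturbationSpec(),
    n_persons: int = 2000,
    burn_in: int = 1000,
    seed: int = 0,
) -> NiraResult:
    """Full intervention scan: baseline plus every node × both directions.

    Each condition gets its own seed substream, so adding or removing
    conditions does not shift another condition's draws.
    """
    sd = tau_sd(net)
    conditions = [("__baseline__", "baseline")]
    conditions += [(nid, d) for d in DIRECTIONS for nid in net.item_ids]
    ss = np.random.SeedSequence(seed).spawn(len(conditions))
    rows = []
    for (nid, direction), child in zip(conditions, ss):
        child_seed = int(child.generate_state(1)[0] % 2**31)
        if direction == "baseline":
            sim_net = net
        else:
            sim_net = perturb_thresholds(net, nid, spec, direction)
        scores = simulate_sum_scores(sim_net, n_persons, burn_in, child_seed)
        rows.append(
            {"item_id": nid if direction != "baseline" else "(baseline)",
             "direction": direction, **summarize_sum_scores(scores)}
        )
    table = pd.DataFrame(rows)
    table["rank"] = np.nan
    for direction, ascending in (("aggravate", False), ("alleviate", True)):
        mask = table["direction"] == direction
        order = table.loc[mask, "mean"].rank(ascending=ascending, method="first")
        table.loc[mask, "rank"] = order
    return NiraResult(table, spec.magnitude, sd, seed)
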