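"""Node centrality: strength, expected influence, bridge expected influence.

All three are one-step (direct-edge) indices on the weighted signed
network.  Strength is Σ_j |w_ij|; expected influence (EI) keeps the
signs, Σ_j w_ij; bridge expected influence (BEI) restricts the signed
sum to edges crossing to the other community, so positive BEI marks a
node whose activation promotes the opposite community and negative BEI
one that suppresses it.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .network import IsingNetwork

__all__ = [
    "strength",
    "expected_influence",
    "bridge_expected_influence",
    "centrality_table",
    "zscore_table",
]


def strength(net: IsingNetwork) -> np.ndarray:
    return np.abs(net.W).sum(axis=1)


def expected_influence(net: IsingNetwork) -> np.ndarray:
    return net.W.sum(axis=1)


def bridge_expected_influence(net: IsingNetwork, communities=None) -> np.ndarray:
    """Signed sum of each node's cross-community edge weights."""
    comm = np.asarray(communities if communities is not None else net.communities)
    if comm.shape != (net.p,):
        raise ValueError("every node needs a community label")
    if len(set(comm.tolist())) < 2:
        raise ValueError("bridge expected influence requires >= 2 communities")
    cross = comm[:, None] != comm[None, :]
    return (net.W * cross).sum(axis=1)


def centrality_table(net: IsingNetwork, communities=None) -> pd.DataFrame:
    """Strength, EI and BEI per node, with z-standardized companions."""
    df = pd.DataFrame(
        {
            "item_id": list(net.item_ids),
            "community": list(communities if communities is not None else net.communities),
            "strength": strength(net),
            "expected_influence": expected_influence(net),
            "bridge_expected_influence": bridge_expected_influence(net, communities),
        }
    )
    return zscore_table(df)


def zscore_table(
    table: pd.DataFrame,
    metrics=("strength", "expected_influence", "bridge_expected_influence"),
    ddof: int = 1,
) -> pd.DataFrame:
    """Append z-scored columns ((x − mean)/sd across nodes; sample sd).

    A constant metric has sd 0; its z column is set to all zeros with a
    warning rather than NaN.
    """
    if len(table) < 2:
        raise ValueError("z-scores need at least two nodes")
    out = table.copy()
    for m in metrics:
        if m not in table.columns:
            continue
        x = table[m].to_numpy(dtype=float)
        sd = x.std(ddof=ddof)
        if sd == 0:
            warnings.warn(f"metric {m!r} is constant across nodes; z set to 0",
                          stacklevel=2)
            z = np.zeros_like(x)
        else:
            z = (x - x.mean()) / sd
        out[f"z_{m}"] = z
    return out
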