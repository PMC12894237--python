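"""Ising network container and serialization.

The pairwise Ising model over binary items x ∈ {0,1}^p is

    P(x) ∝ exp( Σ_i τ_i x_i + Σ_{i<j} w_ij x_i x_j )

where ``tau`` holds the node thresholds (intercepts; under 0/1 coding a
more negative threshold means a lower endorsement probability) and ``W``
the symmetric pairwise interaction weights.  Community labels partition
the items into the instruments they came from (e.g. a knowledge scale
and a stigma scale) and drive the bridge-centrality computations.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np

__all__ = ["IsingNetwork", "write_network", "read_network"]

# decimal digits used for any serialized weight/threshold; 17 significant
# digits round-trips IEEE doubles exactly
_FMT = "%.17g"


@dataclass(frozen=True)
class IsingNetwork:
    """Symmetric weight matrix W, threshold vector tau, and node metadata."""

    W: np.ndarray
    tau: np.ndarray
    item_ids: tuple[str, ...]
    communities: tuple[str, ...]

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        tau = np.asarray(self.tau, dtype=float)
        object.__setattr__(self, "W", W)
        object.__setattr__(self, "tau", tau)
        object.__setattr__(self, "item_ids", tuple(self.item_ids))
        object.__setattr__(self, "communities", tuple(self.communities))
        p = W.shape[0]
        if W.shape != (p, p):
            raise ValueError("W must be square")
        if tau.shape != (p,):
            raise ValueError("tau length must match W")
        if len(self.item_ids) != p or len(self.communities) != p:
            raise ValueError("item_ids/communities length must match W")
        if len(set(self.item_ids)) != p:
            raise ValueError("item_ids must be unique")
        if not np.all(np.isfinite(W)) or not np.all(np.isfinite(tau)):
            raise ValueError("network parameters must be finite")
        if not np.allclose(W, W.T, atol=1e-12):
            raise ValueError("W must be symmetric")
        if np.any(np.diag(W) != 0):
            raise ValueError("W must have zero diagonal")

    @property
    def p(self) -> int:
        return self.W.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.W, 1)))

    def edges(self) -> list[tuple[int, int, float]]:
        """Nonzero upper-triangle entries as (i, j, weight), i < j."""
        i_idx, j_idx = np.nonzero(np.triu(self.W, 1))
        return [(int(i), int(j), float(self.W[i, j])) for i, j in zip(i_idx, j_idx)]

    def with_tau(self, tau: np.ndarray) -> "IsingNetwork":
        return replace(self, tau=np.asarray(tau, dtype=float))

    def equals(self, other: "IsingNetwork") -> bool:
        return (
            self.item_ids == other.item_ids
            and self.communities == other.communities
            and np.array_equal(self.W, other.W)
            and np.array_equal(self.tau, other.tau)
        )


def _to_dict(net: IsingNetwork) -> dict:
    return {
        "nodes": [
            {"id": nid, "threshold": float(t), "community": c}
            for nid, t, c in zip(net.item_ids, net.tau, net.communities)
        ],
        "edges": [
            {"source": net.item_ids[i], "target": net.item_ids[j], "weight": w}
            for i, j, w in net.edges()
        ],
    }


def _from_dict(d: dict) -> IsingNetwork:
    ids = [n["id"] for n in d["nodes"]]
    tau = np.array([n["threshold"] for n in d["nodes"]], dtype=float)
    comm = [n["community"] for n in d["nodes"]]
    idx = {nid: k for k, nid in enumerate(ids)}
    W = np.zeros((len(ids), len(ids)))
    for e in d["edges"]:
        i, j = idx[e["source"]], idx[e["target"]]
        W[i, j] = W[j, i] = float(e["weight"])
    return IsingNetwork(W, tau, ids, comm)


def write_network(net: IsingNetwork, path: str | Path, format: str = "json") -> None:
    """Serialize a network losslessly.

    Formats: ``json`` (single self-contained file), ``graphml`` (networkx,
    thresholds and communities as node attributes), ``edgelist`` (a
    ``source,target,weight`` CSV plus a ``<path>.nodes.csv`` sidecar
    holding thresholds and community labels, since an edge list alone
    cannot carry node attributes).
    """
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(_to_dict(net), indent=1, default=float))
    elif format == "graphml":
        g = nx.Graph()
        for nid, t, c in zip(net.item_ids, net.tau, net.communities):
            g.add_node(nid, threshold=float(t), community=c)
        for i, j, w in net.edges():
            g.add_edge(net.item_ids[i], net.item_ids[j], weight=float(w))
        nx.write_graphml(g, path)
    elif format == "edgelist":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["source", "target", "weight"])
            for i, j, wt in net.edges():
                w.writerow([net.item_ids[i], net.item_ids[j], _FMT % wt])
        with open(path.with_suffix(path.suffix + ".nodes.csv"), "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["id", "threshold", "community"])
            for nid, t, c in zip(net.item_ids, net.tau, net.communities):
                w.writerow([nid, _FMT % t, c])
    else:
        raise ValueError(f"unknown network format: {format!r}")


def read_network(path: str | Path, format: str = "json") -> IsingNetwork:
    """Inverse of :func:`write_network`; exact on weights and thresholds."""
    path = Path(path)
    if format == "json":
        return _from_dict(json.loads(path.read_text()))
    if format == "graphml":
        g = nx.read_graphml(path)
        ids = list(g.nodes)
        d = {
            "nodes": [
                {
                    "id": nid,
                    "threshold": g.nodes[nid]["threshold"],
                    "community": g.nodes[nid]["community"],
                }
                for nid in ids
            ],
            "edges": [
                {"source": u, "target": v, "weight": g.edges[u, v]["weight"]}
                for u, v in g.edges
            ],
        }
        return _from_dict(d)
    if format == "edgelist":
        nodes_path = path.with_suffix(path.suffix + ".nodes.csv")
        with open(nodes_path, newline="") as fh:
            nodes = [
                {"id": r["id"], "threshold": float(r["threshold"]), "community": r["community"]}
                for r in csv.DictReader(fh)
            ]
        with open(path, newline="") as fh:
            edges = [
                {"source": r["source"], "target": r["target"], "weight": float(r["weight"])}
                for r in csv.DictReader(fh)
            ]
        return _from_dict({"nodes": nodes, "edges": edges})
    raise ValueError(f"unknown network format: {format!r}")
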