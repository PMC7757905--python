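"""Cluster quality measures: conductance, motif conductance, and retrieval scores.

Conductance of a node set S is the cut weight divided by the smaller side's
volume; motif conductance replaces edges by motif instances (hyperedges):
phi_M(S) = cut_M(S) / min(vol_M(S), vol_M(V-S)), where cut_M counts hyperedges
with endpoints on both sides and vol_M counts hyperedge endpoints per side.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .errors import UndefinedConductanceError
from .hypergraph import Graph, Hypergraph, motif_volume

__all__ = [
    "conductance",
    "motif_cut",
    "motif_conductance",
    "ClusterEval",
    "cluster_eval",
]


def conductance(G: Graph, S: Iterable[int]) -> float:
    """Weighted conductance phi(S) = cut(S) / min(vol(S), vol(V-S)).

    Volumes use weighted degrees; the cut is the summed weight of edges with
    one endpoint on each side.  Raises when either side has zero volume.
    """
    if G.directed:
        raise ValueError("conductance is defined for undirected graphs")
    S = set(S)
    extra = S - G.nodes
    if extra:
        raise KeyError(f"nodes {sorted(extra)} not in graph")
    cut = 0.0
    vol_in = 0.0
    vol_out = 0.0
    for i, (u, v) in enumerate(G.edges):
        w = G.weight(i)
        u_in, v_in = u in S, v in S
        if u_in != v_in:
            cut += w
        vol_in += w * (u_in + v_in)
        vol_out += w * ((not u_in) + (not v_in))
    minvol = min(vol_in, vol_out)
    if minvol == 0:
        raise UndefinedConductanceError("min-side volume is zero")
    return cut / minvol


def motif_cut(H: Hypergraph, S: Iterable[int]) -> int:
    """Number of hyperedges with at least one endpoint in S and one outside."""
    S = set(S)
    count = 0
    for e in H.edges:
        inside = sum(1 for v in e if v in S)
        if 0 < inside < len(e):
            count += 1
    return count


def motif_conductance(H: Hypergraph, S: Iterable[int]) -> float:
    """Motif conductance phi_M(S) = cut_M(S) / min(vol_M(S), vol_M(V-S)).

    Volumes count hyperedge endpoints (incidences) per side.  Raises
    :class:`UndefinedConductanceError` when the smaller side has no endpoints.
    """
    S = set(S)
    extra = S - H.nodes
    if extra:
        raise KeyError(f"nodes {sorted(extra)} not in hypergraph")
    vol_in = motif_volume(H, S)
    vol_out = motif_volume(H, H.nodes - S)
    minvol = min(vol_in, vol_out)
    if minvol == 0:
        raise UndefinedConductanceError("min-side motif volume is zero")
    return motif_cut(H, S) / minvol


@dataclass(frozen=True)
class ClusterEval:
    """Precision / recall / F1 of a found cluster against a reference set."""

    precision: float
    recall: float
    f1: float


def cluster_eval(found: Iterable[int], truth: Iterable[int]) -> ClusterEval:
    """Score ``found`` against ``truth`` by precision, recall and F1."""
    found = set(found)
    truth = set(truth)
    if not truth:
        raise ValueError("truth set must be nonempty")
    if not found:
        return ClusterEval(0.0, 0.0, 0.0)
    hit = len(found & truth)
    precision = hit / len(found)
    recall = hit / len(truth)
    denom = precision + recall
    f1 = 2 * precision * recall / denom if denom > 0 else 0.0
    return ClusterEval(precision, recall, f1)
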