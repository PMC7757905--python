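"""Motif enumeration and the motif adjacency matrix.

Builds the motif hypergraph of a host graph — one hyperedge per motif
instance — for the built-in three-node patterns, and the weighted motif
adjacency matrix W_M whose entry (i, j) counts the motif instances containing
both i and j (the clique-expansion weighting used by CRD-M).
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import HgcrdError
from .hypergraph import Graph, Hypergraph

__all__ = ["MotifSpec", "enumerate_motifs", "motif_adjacency", "TRIANGLE", "M1", "M2", "M3"]


@dataclass(frozen=True)
class MotifSpec:
    """One of the built-in 3-node motifs.

    ``triangle`` is the undirected 3-clique.  The directed patterns follow the
    usual triad taxonomy: M1 is a triangle in any direction (every pair joined
    by at least one arc), M2 a directed 3-cycle, M3 a feed-forward loop.
    """

    name: str
    size: int = 3
    directed: bool = False

    def __post_init__(self) -> None:
        if self.name not in ("triangle", "M1", "M2", "M3"):
            raise ValueError(f"unknown motif {self.name!r}")
        if self.size != 3:
            raise ValueError("built-in motifs are 3-node patterns")
        expect_directed = self.name != "triangle"
        if self.directed != expect_directed:
            raise ValueError(f"motif {self.name} requires directed={expect_directed}")


TRIANGLE = MotifSpec("triangle", directed=False)
M1 = MotifSpec("M1", directed=True)
M2 = MotifSpec("M2", directed=True)
M3 = MotifSpec("M3", directed=True)

_BY_NAME = {"triangle": TRIANGLE, "M1": M1, "M2": M2, "M3": M3}


def motif_by_name(name: str) -> MotifSpec:
    try:
        return _BY_NAME[name]
    except KeyError:
        raise ValueError(f"unknown motif {name!r}") from None


def _triple_matches(motif: MotifSpec, a: int, b: int, c: int, arcs: set[tuple[int, int]]) -> bool:
    # All candidates already have every pair connected in the undirected
    # skeleton; only orientation predicates remain.
    if motif.name in ("triangle", "M1"):
        return True
    if motif.name == "M2":  # directed 3-cycle in either rotation
        return ((a, b) in arcs and (b, c) in arcs and (c, a) in arcs) or (
            (a, c) in arcs and (c, b) in arcs and (b, a) in arcs
        )
    # M3: feed-forward loop x->y, x->z, y->z for some labelling
    for x, y, z in ((a, b, c), (a, c, b), (b, a, c), (b, c, a), (c, a, b), (c, b, a)):
        if (x, y) in arcs and (x, z) in arcs and (y, z) in arcs:
            return True
    return False


def enumerate_motifs(G: Graph, motif: MotifSpec) -> Hypergraph:
    """Enumerate motif instances of ``G`` as the motif hypergraph.

    Each unordered node triple satisfying the pattern is emitted exactly once,
    regardless of how many arc orientations realize it, in lexicographic order
    of the sorted triple.  The hypergraph keeps ``G``'s full node set, so
    nodes in no motif instance appear as isolated nodes.
    """
    if G.directed != motif.directed:
        kind = "directed" if motif.directed else "undirected"
        raise HgcrdError(f"motif {motif.name} requires an {kind} host graph")
    adj = G.adjacency()  # undirected skeleton
    arcs: set[tuple[int, int]] = set()
    if G.directed:
        arcs = set(G.edges)
    edges: list[tuple[int, int, int]] = []
    for a in sorted(G.nodes):
        higher = {v for v in adj[a] if v > a}
        for b in sorted(higher):
            for c in sorted(higher & adj[b]):
                if c > b and _triple_matches(motif, a, b, c, arcs):
                    edges.append((a, b, c))
    return Hypergraph(edges=list(edges), nodes=set(G.nodes))


def motif_adjacency(H: Hypergraph) -> Graph:
    """Weighted, undirected co-occurrence graph W_M of a hypergraph.

    W_M(i, j) is the number of hyperedges containing both i and j; the
    diagonal is implicitly zero.
    """
    counts: dict[tuple[int, int], int] = {}
    for e in H.edges:
        for i, u in enumerate(e):
            for v in e[i + 1 :]:
                counts[(u, v)] = counts.get((u, v), 0) + 1
    pairs = sorted(counts)
    return Graph(
        edges=list(pairs),
        nodes=set(H.nodes),
        directed=False,
        weights=[float(counts[p]) for p in pairs],
    )
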