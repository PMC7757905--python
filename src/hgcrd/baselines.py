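"""Neighborhood baselines for seeded hypergraph cluster retrieval.

Both baselines rank the one-hop hypergraph neighborhood of the seed (all
nodes co-occurring with it in at least one hyperedge) and return the seed
plus the top-k neighbors; they assume the target cluster size k is known.
"""

from __future__ import annotations

from .hypergraph import Hypergraph

__all__ = ["top_neighbors", "best_neighbors"]


def _shared_counts(H: Hypergraph, seed: int) -> dict[int, int]:
    shared: dict[int, int] = {}
    for e_idx in H.incidence.get(seed, []):
        for u in H.edges[e_idx]:
            if u != seed:
                shared[u] = shared.get(u, 0) + 1
    return shared


def _take_top(scored: dict[int, float], k: int) -> list[int]:
    ranked = sorted(scored, key=lambda u: (-scored[u], u))
    return ranked[:k]


def top_neighbors(H: Hypergraph, seed: int, k: int) -> set[int]:
    """Seed plus the k neighbors sharing the most hyperedges with it.

    Ties break by ascending node id; fewer than k candidates returns them all.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if seed not in H.nodes:
        raise KeyError(f"seed {seed} not in hypergraph")
    shared = _shared_counts(H, seed)
    return {seed} | set(_take_top({u: float(c) for u, c in shared.items()}, k))


def best_neighbors(H: Hypergraph, seed: int, k: int) -> set[int]:
    """Seed plus the k neighbors with the highest seed-affinity fraction.

    A neighbor v scores (hyperedges shared with the seed) / eta(v): the
    fraction of v's hyperedges that also contain the seed.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if seed not in H.nodes:
        raise KeyError(f"seed {seed} not in hypergraph")
    shared = _shared_counts(H, seed)
    scored = {u: c / H.eta(u) for u, c in shared.items()}
    return {seed} | set(_take_top(scored, k))
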