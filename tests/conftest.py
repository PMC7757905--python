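"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hgcrd import Graph, Hypergraph, metabolic_fixture

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture
def metabolic() -> Hypergraph:
    return metabolic_fixture()


# -- independent oracles (deliberately naive, no package internals) ---------


def brute_motif_cut(edges: list[tuple[int, ...]], S: set[int]) -> int:
    """Count hyperedges straddling S by direct membership inspection."""
    n = 0
    for e in edges:
        ins = [v for v in e if v in S]
        if ins and len(ins) < len(e):
            n += 1
    return n


def brute_motif_phi(edges: list[tuple[int, ...]], nodes: set[int], S: set[int]) -> float | None:
    """Motif conductance from first principles; None when undefined."""
    vol_in = sum(1 for e in edges for v in e if v in S)
    vol_out = sum(1 for e in edges for v in e if v not in S)
    minvol = min(vol_in, vol_out)
    if minvol == 0:
        return None
    return brute_motif_cut(edges, S) / minvol


def brute_triangles(n_nodes: int, edge_set: set[tuple[int, int]]) -> list[tuple[int, int, int]]:
    """All undirected triangles by testing every node triple."""
    from itertools import combinations

    def has(a, b):
        return (min(a, b), max(a, b)) in edge_set

    return [
        (a, b, c)
        for a, b, c in combinations(range(n_nodes), 3)
        if has(a, b) and has(a, c) and has(b, c)
    ]


# -- random instance helpers ------------------------------------------------


def random_graph(rng: np.random.Generator, n: int, p: float) -> Graph:
    """Erdos-Renyi undirected graph on nodes 0..n-1."""
    edges = [
        (a, b) for a in range(n) for b in range(a + 1, n) if rng.random() < p
    ]
    return Graph(edges=edges, nodes=set(range(n)))


def random_hypergraph(
    rng: np.random.Generator, n: int, m: int, sizes: tuple[int, ...] = (2, 3, 4)
) -> Hypergraph:
    """Random multi-hypergraph with hyperedge sizes drawn from ``sizes``."""
    edges = []
    for _ in range(m):
        k = int(rng.choice(sizes))
        k = min(k, n)
        members = rng.choice(n, size=k, replace=False)
        edges.append(tuple(sorted(int(v) for v in members)))
    return Hypergraph(edges=edges, nodes=set(range(n)))
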