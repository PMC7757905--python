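"""Synthetic hypergraphs and benchmark graphs used throughout the test suite.

Everything here is generated in memory from an explicit seed:

* :func:`metabolic_fixture` — the small metabolic motif hypergraph (nine
  3-node hyperedges over metabolites 1..10) used as the worked example;
* :func:`triangle_path_family` — the path-of-triangles localization family: p
  triangle-paths hanging off a hub, with a sparse triangle bridge to a dense
  outside clique;
* :func:`planted_hypergraph` — a two-(or more-)block planted-partition
  hypergraph with within/cross hyperedge probabilities;
* :func:`lfr_sweep` — LFR benchmark graphs with planted power-law
  communities across a range of mixing parameters.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import networkx as nx
import numpy as np

from .errors import GenerationError
from .hypergraph import Graph, Hypergraph

__all__ = [
    "PlantedSpec",
    "metabolic_fixture",
    "triangle_path_family",
    "planted_hypergraph",
    "lfr_sweep",
]

logger = logging.getLogger(__name__)

# Nine metabolic motif instances over metabolites 1..10 (a reaction motif
# M1 + M2 -> M3 gives one 3-node hyperedge per reaction).
_METABOLIC_EDGES: tuple[tuple[int, int, int], ...] = (
    (1, 2, 5),
    (2, 3, 5),
    (3, 4, 5),
    (4, 5, 10),
    (2, 3, 4),
    (1, 6, 7),
    (1, 7, 8),
    (5, 6, 7),
    (6, 8, 9),
)


def metabolic_fixture() -> Hypergraph:
    """The 9-hyperedge metabolic motif hypergraph on nodes 1..10."""
    return Hypergraph(edges=[tuple(e) for e in _METABOLIC_EDGES])


def triangle_path_family(p: int, l: int) -> tuple[Graph, set[int]]:
    """Path-of-triangles localization family.

    Builds ``p`` paths of ``l`` edge-sharing triangles, each attached to a hub
    node u by one further triangle; u is additionally tied by a single bridge
    triangle {u, v, w} to an external node v that fronts a dense clique of
    size 2l.  Returns the undirected graph and the target cluster
    B = {u} + all path nodes.  The only motif route out of B is the one
    bridge triangle, so a local diffusion seeded at u should stay in B.
    """
    if p < 2 or l < 1:
        raise ValueError("need p >= 2 paths and l >= 1 triangles per path")
    hub = 0
    next_id = 1
    edges: list[tuple[int, int]] = []
    B: set[int] = {hub}
    for _ in range(p):
        chain = list(range(next_id, next_id + l + 2))
        next_id += l + 2
        B.update(chain)
        edges.append((hub, chain[0]))
        edges.append((hub, chain[1]))
        for a, b in zip(chain, chain[1:]):
            edges.append((a, b))
        for a, b in zip(chain, chain[2:]):
            edges.append((a, b))
    v = next_id
    w = next_id + 1
    next_id += 2
    edges += [(hub, v), (hub, w), (v, w)]
    clique = list(range(next_id, next_id + 2 * l))
    for q in clique:
        edges.append((v, q))
    for a, b in combinations(clique, 2):
        edges.append((a, b))
    return Graph(edges=edges), B


@dataclass(frozen=True)
class PlantedSpec:
    """Planted-partition hypergraph settings.

    Every candidate hyperedge of ``edge_size`` nodes lying inside one block is
    sampled with probability ``p_in``; candidates spanning blocks with
    ``p_out``.  Candidate spaces larger than ``candidate_cap`` are uniformly
    subsampled before the coin flips.
    """

    block_sizes: tuple[int, ...]
    p_in: float
    p_out: float
    edge_size: int = 3
    rng_seed: int = 0
    candidate_cap: int = 200_000

    def __post_init__(self) -> None:
        if not self.block_sizes or any(s < 1 for s in self.block_sizes):
            raise ValueError("block sizes must be positive")
        if not (0.0 <= self.p_out < self.p_in <= 1.0):
            raise ValueError("need 0 <= p_out < p_in <= 1")
        if self.edge_size < 2:
            raise ValueError("edge_size must be >= 2")


def planted_hypergraph(spec: PlantedSpec) -> tuple[Hypergraph, list[set[int]]]:
    """Sample a planted-partition hypergraph; returns it with its blocks."""
    n = sum(spec.block_sizes)
    rng = np.random.default_rng(spec.rng_seed)
    block_of: dict[int, int] = {}
    blocks: list[set[int]] = []
    start = 0
    for b, size in enumerate(spec.block_sizes):
        members = set(range(start, start + size))
        blocks.append(members)
        for v in members:
            block_of[v] = b
        start += size

    total = math.comb(n, spec.edge_size)
    if total <= spec.candidate_cap:
        candidates = combinations(range(n), spec.edge_size)
    else:
        seen: set[tuple[int, ...]] = set()
        while len(seen) < spec.candidate_cap:
            draw = rng.choice(n, size=spec.edge_size, replace=False)
            seen.add(tuple(sorted(int(x) for x in draw)))
        candidates = iter(sorted(seen))

    edges: list[tuple[int, ...]] = []
    for cand in candidates:
        within = len({block_of[v] for v in cand}) == 1
        prob = spec.p_in if within else spec.p_out
        if prob > 0 and rng.random() < prob:
            edges.append(tuple(cand))
    if not edges:
        raise GenerationError("planted hypergraph came out empty; increase p_in")
    return Hypergraph(edges=edges, nodes=set(range(n))), blocks


_LFR_DEFAULTS = {
    "n": 1000,
    "tau1": 2.0,  # degree exponent
    "tau2": 1.1,  # community-size exponent (generator requires > 1)
    "average_degree": 10,
    "max_degree": 50,
    "min_community": 20,
    "max_community": 100,
}


def lfr_sweep(
    mu_values: Sequence[float],
    base_params: dict | None = None,
    rng_seed: int = 0,
    attempts: int = 5,
) -> list[tuple[float, Graph, list[set[int]]]]:
    """LFR benchmark graphs across mixing parameters.

    Returns one ``(mu, graph, communities)`` triple per feasible mu; a mu for
    which the generator repeatedly fails to converge is logged and skipped.
    Output is a pure function of ``mu_values``, ``base_params`` and
    ``rng_seed``.
    """
    params = dict(_LFR_DEFAULTS)
    if base_params:
        params.update(base_params)
    rng = np.random.default_rng(rng_seed)
    out: list[tuple[float, Graph, list[set[int]]]] = []
    for mu in mu_values:
        if not (0.0 <= mu < 1.0):
            raise ValueError("each mu must lie in [0, 1)")
        built = None
        for _ in range(attempts):
            seed = int(rng.integers(0, 2**31 - 1))
            try:
                built = nx.LFR_benchmark_graph(
                    n=params["n"],
                    tau1=params["tau1"],
                    tau2=params["tau2"],
                    mu=mu,
                    average_degree=params["average_degree"],
                    max_degree=params["max_degree"],
                    min_community=params["min_community"],
                    max_community=params["max_community"],
                    seed=seed,
                )
                break
            except (nx.ExceededMaxIterations, nx.NetworkXError) as err:
                logger.warning("LFR generation failed for mu=%.3f: %s", mu, err)
        if built is None:
            logger.warning("skipping infeasible mu=%.3f", mu)
            continue
        built.remove_edges_from(nx.selfloop_edges(built))
        communities = {frozenset(built.nodes[v]["community"]) for v in built}
        graph = Graph(
            edges=[(int(u), int(v)) for u, v in built.edges()],
            nodes={int(v) for v in built.nodes()},
        )
        out.append((mu, graph, [set(c) for c in communities]))
    return out
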