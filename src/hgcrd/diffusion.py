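"""Capacity-releasing flow diffusion over hyperedges (HG-CRD) and variants.

The algorithm finds a well-connected cluster around a seed node by a
push-relabel style integer flow process.  The seed starts with flow equal to
twice its motif degree; in each outer iteration every node's flow is doubled
("capacity releasing"), an inner push-relabel routine spreads excess flow
across hyperedges under per-hyperedge capacities and node levels, a sweep cut
over the resulting levels proposes a cluster, and excess flow is truncated.
The process stops once truncation removed so much flow that a bottleneck —
the cluster boundary — must have been hit.

Three entry points share the same engine:

* :func:`hgcrd` — diffusion directly on a hypergraph (hyperedges = motifs);
* :func:`crd` — the classical edge diffusion, realised on the 2-uniform
  hypergraph of a graph's edges;
* :func:`crd_m` — edge diffusion on the motif adjacency matrix W_M, with edge
  capacities and degrees scaled by motif co-occurrence counts, evaluated by
  motif conductance on the motif hypergraph.
"""

from __future__ import annotations

import heapq
import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

from .errors import EmptySweepError, NoMotifAtSeedError
from .hypergraph import Graph, Hypergraph, motif_degree
from .metrics import motif_conductance
from .motifs import MotifSpec, motif_adjacency, enumerate_motifs

__all__ = [
    "DiffusionParams",
    "DiffusionState",
    "SweepResult",
    "ClusterResult",
    "hgcrd",
    "hgcrd_inner",
    "is_eligible",
    "sweep_cut",
    "crd",
    "crd_m",
    "excess_cluster",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DiffusionParams:
    """Parameters of the diffusion.

    Either ``phi`` (the target conductance scale) or both ``capacity`` (C)
    and ``max_level`` (h) must be given; explicit C/h win over values derived
    from phi.  Derivations: C = ceil(1/phi) and h = ceil(3 ln(F) / phi) where
    F is the total flow at the start of an inner run.

    ``tau`` (> 1) controls the bottleneck stopping test: the outer loop stops
    once the flow retained after excess truncation drops to 1/tau of the
    no-bottleneck total 2 d_M(s) 2^j.  ``iterations`` (t) caps the number of
    doubling rounds; ``alpha`` is the number of strictly-lower-level
    co-members a hyperedge needs before a node may push through it.
    """

    phi: float | None = None
    capacity: int | None = None
    max_level: int | None = None
    tau: float = 2.0
    iterations: int = 20
    alpha: int = 1

    def __post_init__(self) -> None:
        if self.phi is not None and not (0.0 < self.phi <= 1.0):
            raise ValueError("phi must lie in (0, 1]")
        if self.phi is None and (self.capacity is None or self.max_level is None):
            raise ValueError("give phi, or both capacity and max_level")
        if self.capacity is not None and self.capacity < 1:
            raise ValueError("capacity must be >= 1")
        if self.max_level is not None and self.max_level < 1:
            raise ValueError("max_level must be >= 1")
        if not self.tau > 1.0:
            raise ValueError("tau must exceed 1")
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")
        if self.alpha < 1:
            raise ValueError("alpha must be >= 1")

    def resolved_capacity(self) -> int:
        if self.capacity is not None:
            return self.capacity
        return max(1, math.ceil(1.0 / self.phi))

    def resolved_max_level(self, total_flow: int) -> int:
        if self.max_level is not None:
            return self.max_level
        return max(1, math.ceil(3.0 * math.log(max(total_flow, 2)) / self.phi))


class DiffusionState:
    """Mutable state of one inner push-relabel run.

    Holds integer node flows m_M(v), hyperedge flows m_M(e), node levels
    l(v) and the active queue.  Flows and levels default to zero for nodes
    the diffusion has not touched, which keeps the state local.
    """

    def __init__(
        self,
        H: Hypergraph,
        node_flow: dict[int, int],
        capacity: int,
        max_level: int,
        degree_fn: Callable[[int], int] | None = None,
        edge_weight: Sequence[int] | None = None,
    ):
        self.H = H
        self.node_flow = dict(node_flow)
        self.edge_flow: dict[int, int] = {}
        self.level: dict[int, int] = {}
        self.capacity = capacity
        self.max_level = max_level
        self.edge_weight = edge_weight
        self._degree_fn = degree_fn or (lambda v: motif_degree(H, v))
        self._deg_cache: dict[int, int] = {}
        # queue: (level, insertion counter, node) with lazy invalidation
        self._heap: list[tuple[int, int, int]] = []
        self._counter = itertools.count()
        self._in_queue: set[int] = set()

    # -- quantities --------------------------------------------------------

    def degree(self, v: int) -> int:
        d = self._deg_cache.get(v)
        if d is None:
            d = self._degree_fn(v)
            self._deg_cache[v] = d
        return d

    def excess(self, v: int) -> int:
        return max(self.node_flow.get(v, 0) - self.degree(v), 0)

    def weight(self, e_idx: int) -> int:
        return 1 if self.edge_weight is None else self.edge_weight[e_idx]

    def residual(self, e_idx: int, v: int) -> int:
        """Residual capacity r(e) = min(l(v), C) * w_e - m_M(e) for sender v."""
        lv = self.level.get(v, 0)
        return min(lv, self.capacity) * self.weight(e_idx) - self.edge_flow.get(e_idx, 0)

    def activation_threshold(self, v: int) -> int:
        """Minimum excess that lets v push on some incident hyperedge."""
        inc = self.H.incidence.get(v, [])
        if not inc:
            return -1
        return min(len(self.H.edges[i]) - 1 for i in inc)

    def total_flow(self) -> int:
        return sum(self.node_flow.values())

    # -- active queue ------------------------------------------------------

    def enqueue(self, v: int) -> None:
        if v not in self._in_queue:
            self._in_queue.add(v)
            heapq.heappush(self._heap, (self.level.get(v, 0), next(self._counter), v))

    def requeue(self, v: int) -> None:
        self._in_queue.add(v)
        heapq.heappush(self._heap, (self.level.get(v, 0), next(self._counter), v))

    def dequeue(self, v: int) -> None:
        self._in_queue.discard(v)

    def pop_lowest(self) -> int | None:
        """Lowest-level active node, FIFO among equal levels; None when done."""
        while self._heap:
            lvl, _, v = heapq.heappop(self._heap)
            if v in self._in_queue and lvl == self.level.get(v, 0):
                self._in_queue.discard(v)
                return v
        return None

    @property
    def active(self) -> frozenset[int]:
        return frozenset(self._in_queue)


@dataclass(frozen=True)
class SweepResult:
    """Level-ordered sweep over the diffusion's support."""

    order: tuple[int, ...]
    prefix_phi: tuple[float | None, ...]
    best_set: frozenset[int]
    best_phi: float


@dataclass
class ClusterResult:
    """Outcome of one diffusion run."""

    cluster: frozenset[int]
    phi_star: float
    excess_cluster: frozenset[int]
    iterations_run: int
    terminated_by: str  # "bottleneck" or "iteration-cap"
    history: list[dict] = field(default_factory=list)
    trace: list[dict] | None = None


# -- eligibility and the inner routine -------------------------------------


def is_eligible(state: DiffusionState, v: int, e_idx: int, params: DiffusionParams) -> bool:
    """True iff node v may push flow through hyperedge e right now.

    Requires at least ``alpha`` co-members of e strictly below v's level,
    positive residual capacity, and excess at v of at least |e| - 1 (one unit
    per receiver).
    """
    e = state.H.edges[e_idx]
    if v not in e:
        raise ValueError(f"node {v} not in hyperedge {e_idx}")
    lv = state.level.get(v, 0)
    lower = sum(1 for u in e if u != v and state.level.get(u, 0) < lv)
    if lower < params.alpha:
        return False
    if state.residual(e_idx, v) <= 0:
        return False
    return state.excess(v) >= len(e) - 1


def _pick_eligible(state: DiffusionState, v: int, params: DiffusionParams) -> int | None:
    """Lowest-index eligible hyperedge in v's incidence list (file order)."""
    for e_idx in state.H.incidence.get(v, []):
        if is_eligible(state, v, e_idx, params):
            return e_idx
    return None


def hgcrd_inner(
    H: Hypergraph,
    state: DiffusionState,
    params: DiffusionParams,
    trace: list[dict] | None = None,
) -> dict[int, int]:
    """One push-relabel pass; mutates ``state`` and returns the level map.

    Active nodes (excess at least one receiver-set's worth) push integer flow
    through eligible hyperedges: a push of Psi units debits the sender by
    (|e|-1) Psi and credits each co-member with Psi, bounded by the sender's
    excess, the hyperedge residual and each receiver's 2 d_M(u) headroom.
    A node with no eligible hyperedge (or a zero-size push) is relabelled;
    at level h it leaves the process.  Terminates when no node is active.
    """
    h = state.max_level
    for v in sorted(state.node_flow):
        if state.degree(v) >= 0 and state.activation_threshold(v) >= 0:
            if state.excess(v) >= state.activation_threshold(v) and state.level.get(v, 0) < h:
                state.enqueue(v)
    while True:
        v = state.pop_lowest()
        if v is None:
            break
        e_idx = _pick_eligible(state, v, params)
        pushed = False
        if e_idx is not None:
            e = state.H.edges[e_idx]
            receivers = [u for u in e if u != v]
            psi = min(
                state.excess(v) // (len(e) - 1),
                state.residual(e_idx, v),
                min(2 * state.degree(u) - state.node_flow.get(u, 0) for u in receivers),
            )
            if psi > 0:
                pushed = True
                state.edge_flow[e_idx] = state.edge_flow.get(e_idx, 0) + psi
                state.node_flow[v] = state.node_flow.get(v, 0) - (len(e) - 1) * psi
                for u in receivers:
                    state.node_flow[u] = state.node_flow.get(u, 0) + psi
                if trace is not None:
                    trace.append(
                        {
                            "event": "push",
                            "node": v,
                            "edge": e_idx,
                            "psi": psi,
                            "level": state.level.get(v, 0),
                        }
                    )
                for u in receivers:
                    if (
                        state.excess(u) >= state.activation_threshold(u)
                        and state.level.get(u, 0) < h
                    ):
                        state.enqueue(u)
                if state.excess(v) >= state.activation_threshold(v):
                    state.requeue(v)
        if not pushed:
            new_level = state.level.get(v, 0) + 1
            state.level[v] = new_level
            if trace is not None:
                trace.append({"event": "relabel", "node": v, "level": new_level})
            if new_level < h:
                state.requeue(v)
    return state.level


# -- sweep cut --------------------------------------------------------------


def sweep_cut(
    H: Hypergraph,
    levels: dict[int, int],
    support: Iterable[int],
    node_flow: dict[int, int] | None = None,
) -> SweepResult:
    """Best-motif-conductance prefix of the level-ordered support.

    Support nodes are sorted by level descending (ties: node flow descending,
    then node id ascending); each prefix's motif conductance is evaluated on
    ``H`` and the first minimizing prefix returned.  Prefixes whose smaller
    side has zero motif volume are skipped; if every prefix is skipped an
    :class:`EmptySweepError` is raised.
    """
    support = set(support)
    if not support:
        raise EmptySweepError("empty sweep support")
    flow = node_flow or {}
    order = sorted(support, key=lambda v: (-levels.get(v, 0), -flow.get(v, 0), v))

    total_endpoints = sum(len(e) for e in H.edges)
    inside_count: dict[int, int] = {}
    cut = 0
    vol_in = 0
    prefix_phi: list[float | None] = []
    best_phi = math.inf
    best_idx = -1
    for idx, v in enumerate(order):
        for e_idx in H.incidence.get(v, []):
            size = len(H.edges[e_idx])
            c = inside_count.get(e_idx, 0)
            if 0 < c < size:
                cut -= 1
            c += 1
            inside_count[e_idx] = c
            if 0 < c < size:
                cut += 1
        vol_in += H.eta(v)
        minvol = min(vol_in, total_endpoints - vol_in)
        if minvol == 0:
            prefix_phi.append(None)
            continue
        phi = cut / minvol
        prefix_phi.append(phi)
        if phi < best_phi:
            best_phi = phi
            best_idx = idx
    if best_idx < 0:
        raise EmptySweepError("every sweep prefix has undefined conductance")
    return SweepResult(
        order=tuple(order),
        prefix_phi=tuple(prefix_phi),
        best_set=frozenset(order[: best_idx + 1]),
        best_phi=best_phi,
    )


def excess_cluster(state: DiffusionState, H: Hypergraph) -> frozenset[int]:
    """Nodes whose flow meets or exceeds their degree after an inner run.

    Restricted to nodes the diffusion touched (positive flow or level), which
    keeps zero-degree isolated nodes out.
    """
    touched = {v for v, f in state.node_flow.items() if f > 0}
    touched.update(v for v, l in state.level.items() if l > 0)
    return frozenset(v for v in touched if state.node_flow.get(v, 0) >= state.degree(v))


# -- outer loop -------------------------------------------------------------


def _run_diffusion(
    work_H: Hypergraph,
    seed: int,
    params: DiffusionParams,
    sweep_H: Hypergraph,
    degree_fn: Callable[[int], int] | None = None,
    edge_weight: Sequence[int] | None = None,
    trace: bool = False,
) -> ClusterResult:
    if seed not in work_H.nodes:
        raise KeyError(f"seed {seed} not in node set")
    deg = degree_fn or (lambda v: motif_degree(work_H, v))
    d_s = deg(seed)
    if d_s <= 0 or not work_H.incidence.get(seed):
        raise NoMotifAtSeedError(f"seed {seed} participates in no hyperedge")

    capacity = params.resolved_capacity()
    flow: dict[int, int] = {seed: d_s}
    best_set: frozenset[int] | None = None
    best_phi = math.inf
    history: list[dict] = []
    events: list[dict] | None = [] if trace else None
    last_excess: frozenset[int] = frozenset()
    terminated_by = "iteration-cap"
    iterations_run = 0

    for j in range(params.iterations + 1):
        flow = {v: 2 * f for v, f in flow.items()}
        total = sum(flow.values())
        h = params.resolved_max_level(total)
        if events is not None:
            events.append({"event": "iteration", "j": j})
        state = DiffusionState(
            work_H,
            node_flow=flow,
            capacity=capacity,
            max_level=h,
            degree_fn=deg,
            edge_weight=edge_weight,
        )
        hgcrd_inner(work_H, state, params, trace=events)
        flow = {v: f for v, f in state.node_flow.items()}

        support = {v for v, f in flow.items() if f > 0}
        support.update(v for v, l in state.level.items() if l > 0)
        support.add(seed)
        sweep: SweepResult | None
        try:
            sweep = sweep_cut(sweep_H, state.level, support, node_flow=flow)
        except EmptySweepError:
            sweep = None
        if sweep is not None and sweep.best_phi < best_phi:
            best_phi = sweep.best_phi
            best_set = sweep.best_set
        last_excess = frozenset(v for v in support if flow.get(v, 0) >= deg(v))

        # truncate excess, then test for the bottleneck
        flow = {v: min(f, deg(v)) for v, f in flow.items()}
        flow = {v: f for v, f in flow.items() if f > 0}
        retained = sum(flow.values())
        ideal = 2 * d_s * (2**j)
        stop = retained <= ideal / params.tau
        iterations_run = j + 1
        history.append(
            {
                "iteration": j,
                "total_flow": total,
                "retained_flow": retained,
                "ideal_flow": ideal,
                "max_level": h,
                "sweep_phi": None if sweep is None else sweep.best_phi,
                "sweep_size": None if sweep is None else len(sweep.best_set),
                "stopped": stop,
            }
        )
        logger.info(
            "iteration %d: total=%d retained=%d ideal=%d sweep_phi=%s%s",
            j,
            total,
            retained,
            ideal,
            "n/a" if sweep is None else f"{sweep.best_phi:.4f}",
            " [bottleneck]" if stop else "",
        )
        if stop:
            terminated_by = "bottleneck"
            break

    if best_set is None:
        raise EmptySweepError("no sweep prefix had defined conductance in any iteration")
    return ClusterResult(
        cluster=best_set,
        phi_star=motif_conductance(sweep_H, best_set),
        excess_cluster=last_excess,
        iterations_run=iterations_run,
        terminated_by=terminated_by,
        history=history,
        trace=events,
    )


def hgcrd(
    H: Hypergraph, seed: int, params: DiffusionParams, trace: bool = False
) -> ClusterResult:
    """Run the capacity-releasing hypergraph diffusion from ``seed`` on ``H``."""
    return _run_diffusion(H, seed, params, sweep_H=H, trace=trace)


def _pair_hypergraph(G: Graph) -> tuple[Hypergraph, list[int] | None]:
    """2-uniform hypergraph of a graph's edges, with integer weights if any."""
    order = sorted(
        range(len(G.edges)), key=lambda i: (min(G.edges[i]), max(G.edges[i]))
    )
    edges = [tuple(sorted(G.edges[i])) for i in order]
    weights = None
    if G.weights is not None:
        weights = [int(round(G.weights[i])) for i in order]
    return Hypergraph(edges=edges, nodes=set(G.nodes)), weights


def crd(G: Graph, seed: int, params: DiffusionParams, trace: bool = False) -> ClusterResult:
    """Classical capacity-releasing diffusion on a graph's edges (k = 2)."""
    if G.directed:
        raise ValueError("crd requires an undirected graph")
    if params.alpha != 1:
        raise ValueError("alpha must be 1 for the edge diffusion (k = 2)")
    H2, weights = _pair_hypergraph(G)
    if weights is not None:
        raise ValueError("crd runs on unweighted graphs; use crd_m for weighted diffusion")
    return _run_diffusion(H2, seed, params, sweep_H=H2, trace=trace)


def crd_m(
    G: Graph,
    motif: MotifSpec,
    seed: int,
    params: DiffusionParams,
    trace: bool = False,
) -> ClusterResult:
    """Edge diffusion on the motif adjacency matrix W_M of ``G``.

    Each motif-sharing pair (u, v) becomes a diffusion edge with capacity
    scaled by W_M(u, v) (equivalent to W_M(u, v) parallel unit edges), and
    node degrees are the weighted degrees sum_j W_M(v, j).  Sweeps are scored
    by motif conductance on the motif hypergraph, so the result is directly
    comparable with :func:`hgcrd`.
    """
    if params.alpha != 1:
        raise ValueError("alpha must be 1 for the edge diffusion (k = 2)")
    H_M = enumerate_motifs(G, motif)
    W = motif_adjacency(H_M)
    H2, weights = _pair_hypergraph(W)
    wdeg: dict[int, int] = {v: 0 for v in H2.nodes}
    for e_idx, (u, v) in enumerate(H2.edges):
        w = weights[e_idx] if weights is not None else 1
        wdeg[u] += w
        wdeg[v] += w
    if wdeg.get(seed, 0) == 0:
        raise NoMotifAtSeedError(f"seed {seed} appears in no motif instance")
    return _run_diffusion(
        H2,
        seed,
        params,
        sweep_H=H_M,
        degree_fn=wdeg.__getitem__,
        edge_weight=weights,
        trace=trace,
    )
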