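"""Push-relabel diffusion: inner dynamics, sweep cut, variants, invariants."""

import numpy as np
import pytest
from conftest import brute_motif_phi, random_graph, random_hypergraph

from hgcrd import (
    DiffusionParams,
    DiffusionState,
    EmptySweepError,
    Graph,
    Hypergraph,
    NoMotifAtSeedError,
    TRIANGLE,
    crd,
    crd_m,
    enumerate_motifs,
    excess_cluster,
    hgcrd,
    hgcrd_inner,
    is_eligible,
    motif_degree,
    sweep_cut,
)
from hgcrd.diffusion import _pair_hypergraph

SMALL = DiffusionParams(capacity=2, max_level=3, tau=2.0, iterations=5, alpha=1)
STD = DiffusionParams(capacity=3, max_level=3, tau=2.0, iterations=20, alpha=1)


def make_state(H, flows, params, h=None):
    return DiffusionState(
        H,
        node_flow=flows,
        capacity=params.resolved_capacity(),
        max_level=h or params.max_level,
        )


class TestParams:
    def test_phi_derives_capacity_and_level(self):
        p = DiffusionParams(phi=0.25)
        assert p.resolved_capacity() == 4
        # h = ceil(3 ln(F) / phi) at F = e^T m
        assert p.resolved_max_level(100) == int(np.ceil(3 * np.log(100) / 0.25))

    def test_explicit_values_win_over_phi(self):
        p = DiffusionParams(phi=0.25, capacity=2, max_level=2)
        assert p.resolved_capacity() == 2
        assert p.resolved_max_level(10**6) == 2

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"phi": 0.0},
            {"phi": 1.5},
            {},
            {"capacity": 2},
            {"capacity": 2, "max_level": 2, "tau": 1.0},
            {"capacity": 2, "max_level": 2, "alpha": 0},
            {"capacity": 0, "max_level": 2},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            DiffusionParams(**kwargs)


class TestEligibility:
    def test_needs_lower_level_receiver_and_residual_and_excess(self):
        H = Hypergraph(edges=[(0, 1, 2)])
        st = make_state(H, {0: 4}, SMALL)
        st.level[0] = 1
        assert is_eligible(st, 0, 0, SMALL)

    def test_capacity_exhausted_blocks(self):
        H = Hypergraph(edges=[(0, 1, 2)])
        st = make_state(H, {0: 10}, SMALL)
        st.level[0] = 3
        st.edge_flow[0] = SMALL.capacity
        assert not is_eligible(st, 0, 0, SMALL)

    def test_alpha_two_needs_two_lower_receivers(self):
        H = Hypergraph(edges=[(0, 1, 2)])
        params = DiffusionParams(capacity=2, max_level=3, tau=2.0, iterations=5, alpha=2)
        st = make_state(H, {0: 10}, params)
        st.level[0] = 2
        st.level[1] = 2  # only node 2 is strictly below
        assert not is_eligible(st, 0, 0, params)
        st.level[1] = 0
        assert is_eligible(st, 0, 0, params)

    def test_zero_level_sender_has_no_residual(self):
        H = Hypergraph(edges=[(0, 1, 2)])
        st = make_state(H, {0: 10}, SMALL)
        assert not is_eligible(st, 0, 0, SMALL)


class TestInner:
    def test_single_hyperedge_hand_trace(self):
        # seed a with m = 2 d_M(a) = 4 relabels once, then pushes one unit
        H = Hypergraph(edges=[(0, 1, 2)])
        params = DiffusionParams(capacity=2, max_level=3, tau=2.0, iterations=5, alpha=1)
        st = make_state(H, {0: 4}, params)
        trace = []
        levels = hgcrd_inner(H, st, params, trace=trace)
        assert trace[0] == {"event": "relabel", "node": 0, "level": 1}
        assert trace[1] == {"event": "push", "node": 0, "edge": 0, "psi": 1, "level": 1}
        assert st.node_flow == {0: 2, 1: 1, 2: 1}
        assert levels[0] == 1
        assert st.active == frozenset()

    def test_no_excess_means_no_levels(self):
        H = Hypergraph(edges=[(0, 1, 2), (1, 2, 3)])
        st = make_state(H, {0: 3, 1: 4}, SMALL)  # all below d_M + (k-1)
        levels = hgcrd_inner(H, st, SMALL, trace=None)
        assert all(l == 0 for l in levels.values())
        assert st.node_flow == {0: 3, 1: 4}

    def test_toy_first_iteration_pushes_one_unit_per_hyperedge(self):
        # printed toy dynamics: the seed relabels, then sends one unit through
        # each of its three hyperedges
        H = Hypergraph(edges=[(0, 1, 3), (0, 1, 2), (0, 2, 3), (1, 4, 6)])
        st = make_state(H, {0: 2 * motif_degree(H, 0)}, SMALL)
        trace = []
        hgcrd_inner(H, st, SMALL, trace=trace)
        pushes = [t for t in trace if t["event"] == "push"]
        assert [(t["edge"], t["psi"]) for t in pushes] == [(0, 1), (1, 1), (2, 1)]

    def test_hyperedge_saturates_at_capacity(self):
        # one sender with lots of excess can place at most C units per edge
        H = Hypergraph(edges=[(0, 1, 2)], nodes={0, 1, 2})
        big = Hypergraph(edges=[(0, 1, 2)] * 4)  # give 0 degree to hold flow
        st = make_state(big, {0: 2 * motif_degree(big, 0)}, SMALL)
        hgcrd_inner(big, st, SMALL, trace=None)
        assert all(f <= SMALL.capacity for f in st.edge_flow.values())

    def test_flow_conservation_and_caps_random(self):
        rng = np.random.default_rng(17)
        params = DiffusionParams(capacity=2, max_level=4, tau=2.0, iterations=3, alpha=1)
        for _ in range(25):
            H = random_hypergraph(rng, n=int(rng.integers(4, 10)), m=int(rng.integers(2, 12)))
            seeds = [v for v in sorted(H.nodes) if H.eta(v) > 0]
            if not seeds:
                continue
            s = seeds[int(rng.integers(len(seeds)))]
            st = make_state(H, {s: 2 * motif_degree(H, s)}, params)
            before = st.total_flow()
            hgcrd_inner(H, st, params, trace=None)
            assert st.total_flow() == before
            assert all(0 <= f <= params.capacity for f in st.edge_flow.values())
            for v, f in st.node_flow.items():
                assert 0 <= f <= 2 * motif_degree(H, v)
            assert all(0 <= l <= params.max_level for l in st.level.values())


class TestSweepCut:
    def test_orders_by_level_then_flow_then_id(self):
        H = Hypergraph(edges=[(0, 1, 2), (2, 3, 4)])
        levels = {0: 2, 1: 2, 2: 1, 3: 0, 4: 0}
        res = sweep_cut(H, levels, {0, 1, 2, 3, 4}, node_flow={1: 5, 0: 1})
        assert res.order == (1, 0, 2, 3, 4)

    def test_best_matches_prefix_oracle_random(self):
        rng = np.random.default_rng(23)
        for _ in range(30):
            H = random_hypergraph(rng, n=10, m=8)
            support = {v for v in H.nodes if H.eta(v) > 0}
            if not support:
                continue
            levels = {v: int(rng.integers(0, 4)) for v in support}
            flows = {v: int(rng.integers(0, 6)) for v in support}
            try:
                res = sweep_cut(H, levels, support, node_flow=flows)
            except EmptySweepError:
                continue
            order = sorted(support, key=lambda v: (-levels[v], -flows[v], v))
            phis = []
            for i in range(1, len(order) + 1):
                phi = brute_motif_phi(H.edges, H.nodes, set(order[:i]))
                if phi is not None:
                    phis.append((phi, set(order[:i])))
            assert phis, "oracle found no defined prefix but sweep_cut did"
            best = min(p for p, _ in phis)
            assert res.best_phi == pytest.approx(best)
            for phi, S in phis:
                assert res.best_phi <= phi + 1e-12

    def test_all_prefixes_undefined_raises(self):
        H = Hypergraph(edges=[(0, 1)], nodes={0, 1, 2})
        with pytest.raises(EmptySweepError):
            sweep_cut(H, {2: 1}, {2})


class TestHgcrd:
    def test_metabolic_worked_example(self, metabolic):
        params = DiffusionParams(capacity=2, max_level=2, tau=2.0, iterations=5, alpha=1)
        res = hgcrd(metabolic, 7, params)
        assert round(res.phi_star, 2) == 0.27
        from hgcrd import motif_cut

        assert motif_cut(metabolic, res.cluster) == 3
        assert res.iterations_run <= 6
        assert res.terminated_by == "bottleneck"

    def test_disconnected_component_is_recovered_exactly(self):
        H = Hypergraph(edges=[(0, 1, 2), (3, 4, 5)])
        res = hgcrd(H, 0, SMALL)
        assert res.cluster == {0, 1, 2}
        assert res.phi_star == 0.0

    def test_t0_runs_single_iteration(self, metabolic):
        params = DiffusionParams(
            capacity=2, max_level=2, tau=1e9, iterations=0, alpha=1
        )
        res = hgcrd(metabolic, 7, params)
        assert res.iterations_run == 1
        assert res.terminated_by == "iteration-cap"

    def test_seed_without_motif_raises(self):
        H = Hypergraph(edges=[(0, 1, 2)], nodes={0, 1, 2, 9})
        with pytest.raises(NoMotifAtSeedError):
            hgcrd(H, 9, SMALL)

    def test_phi_star_is_cluster_conductance(self, metabolic):
        res = hgcrd(metabolic, 7, SMALL)
        assert res.phi_star == pytest.approx(
            brute_motif_phi(metabolic.edges, metabolic.nodes, set(res.cluster))
        )

    def test_truncation_invariant_in_history(self, metabolic):
        res = hgcrd(metabolic, 7, SMALL)
        d_s = motif_degree(metabolic, 7)
        for row in res.history:
            assert row["retained_flow"] <= row["total_flow"]
            assert row["total_flow"] <= 2 * d_s * 2 ** row["iteration"]


class TestTraceInvariants:
    def replay(self, H, seed, params):
        res = hgcrd(H, seed, params, trace=True)
        # replay every recorded event against an independent bookkeeping of
        # the flows, asserting the per-step caps and monotone levels
        d = {v: motif_degree(H, v) for v in H.nodes}
        flows: dict[int, int] = {seed: d[seed]}
        edge_flow: dict[int, int] = {}
        for ev in res.trace:
            if ev["event"] == "iteration":
                if ev["j"] > 0:  # truncate excess, then the flow doubles
                    flows = {v: min(f, d[v]) for v, f in flows.items()}
                flows = {v: 2 * f for v, f in flows.items()}
                edge_flow = {}  # each inner run is a fresh flow problem
            elif ev["event"] == "push":
                e = H.edges[ev["edge"]]
                v, psi = ev["node"], ev["psi"]
                assert isinstance(psi, int) and psi >= 1
                edge_flow[ev["edge"]] = edge_flow.get(ev["edge"], 0) + psi
                assert edge_flow[ev["edge"]] <= params.capacity
                flows[v] = flows.get(v, 0) - (len(e) - 1) * psi
                assert flows[v] >= 0
                for u in e:
                    if u != v:
                        flows[u] = flows.get(u, 0) + psi
                        assert flows[u] <= 2 * d[u]
            else:
                v = ev["node"]
                assert ev["level"] >= 1
        return res

    def test_trace_respects_caps(self, metabolic):
        self.replay(metabolic, 7, SMALL)

    def test_trace_respects_caps_random(self):
        rng = np.random.default_rng(31)
        for _ in range(5):
            H = random_hypergraph(rng, n=8, m=10, sizes=(3,))
            seeds = [v for v in sorted(H.nodes) if H.eta(v) > 0]
            self.replay(H, seeds[0], SMALL)

    def test_levels_monotone_within_inner_run(self):
        H = Hypergraph(edges=[(0, 1, 2), (1, 2, 3), (2, 3, 4)])
        res = hgcrd(H, 0, SMALL, trace=True)
        # within an inner run each node's relabels step up one at a time
        seen: dict[int, int] = {}
        for ev in res.trace:
            if ev["event"] == "iteration":
                seen = {}
            elif ev["event"] == "relabel":
                v = ev["node"]
                assert ev["level"] == seen.get(v, 0) + 1
                assert ev["level"] <= SMALL.max_level
                seen[v] = ev["level"]


class TestCrdAndReduction:
    def test_triangle_component_recovered_whole(self):
        # no bottleneck inside a triangle: with any outside volume present,
        # the sweep returns the full triangle at zero conductance
        G = Graph(edges=[(0, 1), (1, 2), (0, 2), (3, 4)])
        params = DiffusionParams(capacity=2, max_level=3, tau=2.0, iterations=1, alpha=1)
        res = crd(G, 0, params)
        assert res.cluster == {0, 1, 2}
        assert res.phi_star == 0.0

    def test_whole_graph_support_degenerates_to_defined_prefix(self):
        # when the diffusion covers every node, the full prefix has no
        # complement volume and is skipped; a defined prefix is still returned
        G = Graph(edges=[(0, 1), (1, 2), (0, 2)])
        params = DiffusionParams(capacity=2, max_level=3, tau=2.0, iterations=1, alpha=1)
        res = crd(G, 0, params)
        assert len(res.cluster) >= 1
        assert res.phi_star == 1.0

    def test_star_sweep_matches_oracle(self):
        G = Graph(edges=[(0, 1), (0, 2), (0, 3)])
        res = crd(G, 0, SMALL)
        H2, _ = _pair_hypergraph(G)
        phi = brute_motif_phi(H2.edges, H2.nodes, set(res.cluster))
        assert res.phi_star == pytest.approx(phi)

    def test_alpha_above_one_rejected_for_edges(self):
        G = Graph(edges=[(0, 1)])
        params = DiffusionParams(capacity=2, max_level=2, tau=2.0, iterations=1, alpha=2)
        with pytest.raises(ValueError):
            crd(G, 0, params)

    def test_crd_equals_hgcrd_on_edge_hypergraph_push_for_push(self):
        rng = np.random.default_rng(41)
        for _ in range(10):
            G = random_graph(rng, n=int(rng.integers(4, 12)), p=0.4)
            comps = [v for v in sorted(G.nodes) if G.adjacency()[v]]
            if not comps:
                continue
            seed = comps[0]
            H2, _ = _pair_hypergraph(G)
            a = crd(G, seed, SMALL, trace=True)
            b = hgcrd(H2, seed, SMALL, trace=True)
            assert a.trace == b.trace
            assert a.cluster == b.cluster
            assert a.phi_star == b.phi_star


class TestCrdM:
    def test_single_triangle_equals_plain_crd(self):
        G = Graph(edges=[(0, 1), (1, 2), (0, 2)])
        params = DiffusionParams(capacity=2, max_level=3, tau=2.0, iterations=2, alpha=1)
        a = crd_m(G, TRIANGLE, 0, params)
        b = crd(G, 0, params)
        assert a.cluster == b.cluster

    def test_shared_edge_gets_double_weight(self):
        # two triangles sharing edge (1,2): W_M(1,2) = 2
        G = Graph(edges=[(0, 1), (0, 2), (1, 2), (1, 3), (2, 3)])
        from hgcrd import motif_adjacency

        W = motif_adjacency(enumerate_motifs(G, TRIANGLE))
        lookup = {e: w for e, w in zip(W.edges, W.weights)}
        assert lookup[(1, 2)] == 2.0
        res = crd_m(G, TRIANGLE, 0, SMALL)
        assert res.cluster <= {0, 1, 2, 3}

    def test_weighted_degrees_match_motif_degrees(self):
        rng = np.random.default_rng(53)
        for _ in range(5):
            G = random_graph(rng, 12, p=0.35)
            H = enumerate_motifs(G, TRIANGLE)
            W_nodes = [v for v in sorted(H.nodes) if H.eta(v) > 0]
            if not W_nodes:
                continue
            res = crd_m(G, TRIANGLE, W_nodes[0], SMALL)
            hres = hgcrd(H, W_nodes[0], SMALL)
            # both run on the same degree sequence, so both stay inside the
            # motif-covered part of the graph
            assert all(H.eta(v) > 0 for v in res.cluster)
            assert all(H.eta(v) > 0 for v in hres.cluster)

    def test_seed_outside_all_motifs_raises(self):
        G = Graph(edges=[(0, 1), (1, 2), (0, 2), (2, 3)])
        with pytest.raises(NoMotifAtSeedError):
            crd_m(G, TRIANGLE, 3, SMALL)


class TestExcessCluster:
    def test_seed_keeps_excess_when_stuck(self):
        H = Hypergraph(edges=[(0, 1, 2)])
        params = DiffusionParams(capacity=1, max_level=1, tau=2.0, iterations=0, alpha=1)
        st = make_state(H, {0: 4}, params, h=1)
        hgcrd_inner(H, st, params, trace=None)
        assert 0 in excess_cluster(st, H)

    def test_zero_flow_nodes_excluded(self):
        H = Hypergraph(edges=[(0, 1, 2)], nodes={0, 1, 2, 7})
        st = make_state(H, {0: 4}, SMALL)
        hgcrd_inner(H, st, SMALL, trace=None)
        assert 7 not in excess_cluster(st, H)

    def test_bottleneck_keeps_excess_inside_block(self):
        # a dense triple of hyperedges with one weak bridge out
        H = Hypergraph(
            edges=[(0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3), (3, 4, 5)]
        )
        res = hgcrd(H, 0, DiffusionParams(capacity=2, max_level=2, tau=2.0, iterations=6, alpha=1))
        assert {0, 1, 2, 3} <= res.excess_cluster | res.cluster
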