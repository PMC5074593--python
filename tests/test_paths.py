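"""Shortest/suboptimal path machinery against independent oracles."""

import numpy as np
import networkx as nx
import pytest

import dynapath as dp
from dynapath.paths import (
    EnsembleSizeError,
    _dijkstra,
    all_pairs_optimal,
    bottleneck_edges,
    candidate_nodes_near_site,
    classify_effective,
    optimal_path,
    path_ensemble_betweenness,
    path_statistics,
    select_anchor_pair,
    suboptimal_paths,
)

from conftest import (
    brute_shortest,
    enumerate_simple_paths,
    net_from_corr_edges,
    point_node_model,
    random_network,
)


class TestAllPairsOptimal:
    def test_single_edge(self):
        net = net_from_corr_edges([(0, 1, 0.5)])
        ap = all_pairs_optimal(net)
        assert ap.dist[0, 1] == pytest.approx(np.log(2))
        assert ap.path_nodes(0, 1) == [0, 1]

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_single_source_relaxation(self, seed):
        """Independent-algorithm cross-check: Dijkstra from every node."""
        net = random_network(seed)
        ap = all_pairs_optimal(net)
        for s in range(net.n_nodes):
            d = _dijkstra(net, s)
            assert np.allclose(ap.dist[s], d, atol=1e-9)

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_brute_force_enumeration(self, seed):
        net = random_network(seed, n_max=7)
        ap = all_pairs_optimal(net)
        for s in range(net.n_nodes):
            for t in range(s + 1, net.n_nodes):
                assert ap.dist[s, t] == pytest.approx(
                    brute_shortest(net, s, t), abs=1e-9
                )

    def test_matches_scipy_floyd_warshall(self):
        from scipy.sparse.csgraph import floyd_warshall
        from scipy.sparse import csr_matrix

        net = random_network(12345)
        n = net.n_nodes
        m = np.zeros((n, n))
        for u, v, d in net.graph.edges(data=True):
            m[u, v] = m[v, u] = d["weight"]
        ref = floyd_warshall(csr_matrix(m), directed=False)
        ap = all_pairs_optimal(net)
        assert np.allclose(ap.dist, ref, atol=1e-9)

    def test_disconnection_is_infinite_not_an_error(self):
        net = net_from_corr_edges([(0, 1, 0.9)], n_nodes=3)
        ap = all_pairs_optimal(net)
        assert np.isinf(ap.dist[0, 2])
        assert ap.path_nodes(0, 2) is None
        assert optimal_path(net, 0, 2) is None


class TestOptimalPath:
    def test_forced_chain_closed_form(self):
        """Chain a–b–c with raw weights 0.1 and 0.2: W = 30 on the ×100
        scale and min corr e^{-0.2}."""
        net = net_from_corr_edges(
            [(0, 1, np.exp(-0.1)), (1, 2, np.exp(-0.2))]
        )
        p = optimal_path(net, 0, 2)
        assert p.nodes == (0, 1, 2)
        assert p.weight100 == pytest.approx(30.0)
        assert p.min_corr == pytest.approx(np.exp(-0.2))

    def test_planted_path_recovered(self, planted_model, planted_network):
        p = optimal_path(
            planted_network,
            planted_model.planted_path[0],
            planted_model.planted_path[-1],
        )
        assert p.nodes == planted_model.planted_path

    def test_two_step_route_beats_heavy_shortcut(self):
        net = net_from_corr_edges(
            [(0, 1, 0.9), (1, 2, 0.9), (0, 2, 0.3)]
        )
        p = optimal_path(net, 0, 2)
        assert p.nodes == (0, 1, 2)

    def test_source_equals_sink_rejected(self):
        net = net_from_corr_edges([(0, 1, 0.5)])
        with pytest.raises(ValueError):
            optimal_path(net, 0, 0)


class TestPathStatistics:
    def test_closed_form(self):
        net = net_from_corr_edges([(0, 1, 0.9), (1, 2, 0.8)])
        p = path_statistics(net, [0, 1, 2])
        assert p.n_hops == 2
        assert p.weight100 == pytest.approx(
            100 * (-np.log(0.9) - np.log(0.8)), abs=1e-9
        )
        assert round(p.weight100, 1) == 32.9
        assert p.min_corr == pytest.approx(0.8)

    def test_single_perfect_edge(self):
        net = net_from_corr_edges([(0, 1, 1.0)])
        p = path_statistics(net, [0, 1])
        assert (p.n_hops, p.weight100, p.min_corr) == (1, 0.0, 1.0)

    def test_missing_edge_is_an_error(self):
        net = net_from_corr_edges([(0, 1, 0.9)], n_nodes=3)
        with pytest.raises(ValueError, match="missing"):
            path_statistics(net, [0, 1, 2])

    def test_invariant_bounds(self):
        """100·(−ln min) ≤ W ≤ 100·N·(−ln min) for arbitrary paths."""
        rng = np.random.default_rng(0)
        for _ in range(50):
            corrs = rng.uniform(0.1, 1.0, size=rng.integers(1, 8))
            edges = [(i, i + 1, c) for i, c in enumerate(corrs)]
            net = net_from_corr_edges(edges)
            p = path_statistics(net, list(range(len(corrs) + 1)))
            lo = 100 * -np.log(p.min_corr)
            hi = 100 * p.n_hops * -np.log(p.min_corr)
            assert lo - 1e-9 <= p.weight100 <= hi + 1e-9


class TestClassifyEffective:
    @pytest.mark.parametrize(
        "min_corr,expected",
        [(0.73, True), (0.52, False), (0.7, True)],
    )
    def test_threshold(self, min_corr, expected):
        net = net_from_corr_edges([(0, 1, 0.95), (1, 2, min_corr)])
        rep = classify_effective(path_statistics(net, [0, 1, 2]))
        assert rep.effective is expected
        assert rep.limiting_edge == (1, 2)
        assert rep.limiting_corr == pytest.approx(min_corr)


class TestSuboptimalPaths:
    def test_offset_zero_returns_all_ties(self):
        # diamond with two exactly equal-weight routes
        net = net_from_corr_edges(
            [(0, 1, 0.8), (1, 3, 0.7), (0, 2, 0.8), (2, 3, 0.7)]
        )
        ens = suboptimal_paths(net, 0, 3, offset=0.0)
        assert ens.degeneracy == 2
        assert {p.nodes for p in ens.suboptimals} == {(0, 1, 3), (0, 2, 3)}
        assert ens.optimal in ens.suboptimals

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_brute_force_within_offset(self, seed):
        net = random_network(seed, n_max=8)
        s, t = 0, net.n_nodes - 1
        ens = suboptimal_paths(net, s, t, offset=20.0)
        all_paths = enumerate_simple_paths(net, s, t)
        if not all_paths:
            assert ens is None
            return
        opt = min(p[0] for p in all_paths)
        expected = {
            nodes for length, nodes in all_paths if length <= opt + 0.20 + 1e-9
        }
        assert {p.nodes for p in ens.suboptimals} == expected
        assert all(
            p.weight100 <= ens.optimal.weight100 + 20.0 + 1e-6
            for p in ens.suboptimals
        )
        # betweenness counts sum to the total number of hops
        assert sum(ens.edge_counts.values()) == sum(
            p.n_hops for p in ens.suboptimals
        )

    def test_constructed_detour_within_offset(self):
        # planted two-hop route plus a detour 0.05 raw units longer
        net = net_from_corr_edges(
            [
                (0, 1, 0.9),
                (1, 3, 0.9),
                (0, 2, 0.9),
                (2, 3, 0.9 * np.exp(-0.05)),
            ]
        )
        ens = suboptimal_paths(net, 0, 3, offset=10.0)
        assert {p.nodes for p in ens.suboptimals} == {(0, 1, 3), (0, 2, 3)}
        ens0 = suboptimal_paths(net, 0, 3, offset=1.0)
        assert {p.nodes for p in ens0.suboptimals} == {(0, 1, 3)}

    def test_cap_guards_blowup(self):
        edges = []
        for i in range(8):
            for j in range(i + 1, 8):
                edges.append((i, j, 0.99))
        net = net_from_corr_edges(edges)
        with pytest.raises(EnsembleSizeError):
            suboptimal_paths(net, 0, 7, offset=1e4, cap=10)

    def test_disconnected_pair_returns_none(self):
        net = net_from_corr_edges([(0, 1, 0.9)], n_nodes=3)
        assert suboptimal_paths(net, 0, 2, offset=5.0) is None


class TestEnsembleBetweenness:
    def test_single_path_counts_one(self):
        net = net_from_corr_edges([(0, 1, 0.9), (1, 2, 0.9)])
        ens = suboptimal_paths(net, 0, 2, offset=0.0)
        ranked = path_ensemble_betweenness(ens)
        assert all(c == 1 for _, c in ranked)

    def test_edge_disjoint_paths_have_no_bottleneck(self):
        net = net_from_corr_edges(
            [(0, 1, 0.8), (1, 3, 0.7), (0, 2, 0.8), (2, 3, 0.7)]
        )
        ens = suboptimal_paths(net, 0, 3, offset=0.0)
        assert all(c == 1 for _, c in path_ensemble_betweenness(ens))
        assert bottleneck_edges(ens) == []

    def test_hourglass_middle_edge_carries_everything(self):
        # two routes into node 2, shared middle edge 2-3, two routes out
        net = net_from_corr_edges(
            [
                (0, 1, 0.9), (1, 2, 0.9),
                (0, 6, 0.9), (6, 2, 0.9),
                (2, 3, 0.9),
                (3, 4, 0.9), (4, 5, 0.9),
                (3, 7, 0.9), (7, 5, 0.9),
            ]
        )
        ens = suboptimal_paths(net, 0, 5, offset=0.0)
        assert ens.degeneracy == 4
        assert ens.edge_counts[(2, 3)] == 4
        assert bottleneck_edges(ens) == [(2, 3)]


class TestAnchors:
    def test_site_atom_on_node(self):
        nm = point_node_model(5)
        ref = np.zeros((5, 3))
        ref[:, 0] = np.arange(5) * 20.0
        out = candidate_nodes_near_site(nm, ref, site_atoms=[2], radius=10.0)
        assert out == [2]

    def test_empty_shell_is_an_error(self):
        nm = point_node_model(3)
        ref = np.array([[0.0, 0, 0], [20.0, 0, 0], [40.0, 0, 0]])
        site = np.array([[100.0, 0, 0]])
        coords = np.vstack([ref, site])
        with pytest.raises(ValueError, match="no nodes"):
            candidate_nodes_near_site(nm, coords, site_atoms=[3], radius=10.0)

    def test_exact_shell_membership(self):
        """Exhaustive distance check: exactly the 3 nodes inside 10 Å."""
        nm = point_node_model(6)
        ref = np.zeros((7, 3))
        ref[:6, 0] = [0.0, 4.0, 8.0, 15.0, 30.0, 45.0]
        ref[6] = [1.0, 0.0, 0.0]  # the site atom
        out = candidate_nodes_near_site(nm, ref, site_atoms=[6], radius=10.0)
        assert out == [0, 1, 2]

    def test_singleton_sets_forced_pair(self):
        net = net_from_corr_edges([(0, 1, 0.9), (1, 2, 0.8)])
        res = select_anchor_pair(net, [0], [2])
        assert res is not None
        (a, b), path = res
        assert (a, b) == (0, 2)
        assert path.nodes == (0, 1, 2)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_pair_enumeration(self, seed):
        net = random_network(seed)
        n = net.n_nodes
        set_a, set_b = [0, 1], [n - 2, n - 1]
        res = select_anchor_pair(net, set_a, set_b)
        best = None
        for a in set_a:
            for b in set_b:
                if a == b:
                    continue
                d = brute_shortest(net, a, b)
                if np.isfinite(d) and (best is None or d < best[0] - 1e-12):
                    best = (d, (a, b))
        if best is None:
            assert res is None
        else:
            (a, b), path = res
            assert path.raw_length == pytest.approx(best[0], abs=1e-9)

    def test_all_disconnected_returns_none(self):
        net = net_from_corr_edges([(0, 1, 0.9), (2, 3, 0.9)])
        assert select_anchor_pair(net, [0, 1], [2, 3]) is None
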