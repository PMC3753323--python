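"""Graph diagnostics against closed forms and independent oracles."""

import networkx as nx
import numpy as np
import pytest

from meginet.diagnostics import (
    CV_DIAGNOSTICS,
    DIAGNOSTICS,
    all_diagnostics,
    basic_metrics,
    betweenness_centrality,
    cost_efficiency,
    hierarchy_exponent,
    mean_connection_distance,
    modularity,
    rent_exponent,
    robustness,
    synchronizability,
)


def _adj(g):
    return nx.to_numpy_array(g).astype(bool)


class TestBasicMetrics:
    def test_complete_graph_closed_forms(self):
        m = basic_metrics(_adj(nx.complete_graph(5)))
        assert m["path_length"] == 1.0
        assert m["clustering"] == 1.0
        assert m["global_efficiency"] == 1.0
        assert m["local_efficiency"] == 1.0
        assert m["betweenness"] == 0.0
        assert np.isnan(m["assortativity"])  # regular graph: flagged missing

    def test_six_cycle(self):
        m = basic_metrics(_adj(nx.cycle_graph(6)))
        assert m["path_length"] == pytest.approx(1.8)
        assert m["clustering"] == 0.0
        # BFS oracle: distances 1,1,2,2,3 from each node
        assert m["global_efficiency"] == pytest.approx(
            (2 * 1 + 2 * 0.5 + 1 / 3) / 5
        )

    def test_star_betweenness_and_assortativity(self):
        a = _adj(nx.star_graph(5))
        bc = betweenness_centrality(a)
        assert bc[0] == pytest.approx(1.0)
        np.testing.assert_allclose(bc[1:], 0.0)
        assert basic_metrics(a)["assortativity"] == pytest.approx(-1.0)

    def test_disconnected_pairs_use_documented_conventions(self):
        g = nx.disjoint_union(nx.path_graph(3), nx.path_graph(2))
        m = basic_metrics(_adj(g))
        # L over connected ordered pairs only: P3 gives (1,1,2)x2, P2 gives 1
        assert m["path_length"] == pytest.approx((4 * 1 + 2 * 2 + 2 * 1) / 8)
        # E_glob uses 1/inf = 0 over ALL ordered pairs
        assert m["global_efficiency"] == pytest.approx((4 + 2 * 0.5 + 2) / 20)

    def test_no_edges_rejected(self):
        with pytest.raises(ValueError):
            basic_metrics(np.zeros((4, 4), dtype=bool))


class TestModularity:
    def test_complete_graph_has_zero_modularity(self):
        assert modularity(_adj(nx.complete_graph(6))) == pytest.approx(0.0)

    def test_two_cliques_matches_exhaustive_search(self):
        g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
        g.add_edge(0, 4)
        q = modularity(_adj(g), seed=0)
        # exhaustive optimum: the two cliques as communities
        m = 13.0
        q_opt = 2 * (6 / m - (13 / (2 * m)) ** 2)
        assert q == pytest.approx(q_opt, abs=1e-12)

    def test_invariant_under_relabeling(self, rng):
        g = nx.gnm_random_graph(10, 18, seed=3)
        a = _adj(g)
        perm = rng.permutation(10)
        assert modularity(a, seed=1) == pytest.approx(
            modularity(a[np.ix_(perm, perm)], seed=1), abs=1e-9
        )

    def test_empty_graph_missing(self):
        assert np.isnan(modularity(np.zeros((4, 4), dtype=bool)))


class TestHierarchy:
    def test_regular_graph_with_constant_clustering_is_flat(self):
        beta = hierarchy_exponent(_adj(nx.circulant_graph(10, [1, 2])))
        assert beta == pytest.approx(0.0, abs=1e-9)

    def test_constructed_inverse_power_law(self):
        # C(k) ~ k^-1 over degree classes {2, 4}: a triangle (k=2, C=1)
        # plus the 8-antiprism (k=4, each node's 4 neighbours span 3 of
        # the 6 possible edges, C=1/2).
        g = nx.complete_graph(3)
        h = nx.circulant_graph(8, [1, 2])
        a = _adj(nx.disjoint_union(g, h))
        beta = hierarchy_exponent(a)
        expected = -np.polyfit(np.log([2, 4]), np.log([1.0, 0.5]), 1)[0]
        assert beta == pytest.approx(expected, abs=1e-9)
        assert beta == pytest.approx(1.0, abs=1e-9)

    def test_invariant_to_duplication(self):
        g = nx.gnm_random_graph(9, 16, seed=2)
        a = _adj(g)
        dup = _adj(nx.disjoint_union(g, g))
        b1, b2 = hierarchy_exponent(a), hierarchy_exponent(dup)
        assert (np.isnan(b1) and np.isnan(b2)) or b1 == pytest.approx(b2)


class TestSynchronizability:
    def test_complete_graphs_give_one(self):
        for n in (3, 5, 8):
            assert synchronizability(_adj(nx.complete_graph(n))) == pytest.approx(1.0)

    def test_path_graph_p4_eigendecomposition_oracle(self):
        # Laplacian spectrum of P4: {0, 2-sqrt(2), 2, 2+sqrt(2)}
        s = synchronizability(_adj(nx.path_graph(4)))
        assert s == pytest.approx((2 - np.sqrt(2)) / (2 + np.sqrt(2)))

    def test_bounded_in_unit_interval(self, rng):
        for seed in range(10):
            g = nx.gnm_random_graph(10, 16, seed=seed)
            s = synchronizability(_adj(g))
            if not np.isnan(s):
                assert 0 < s <= 1 + 1e-12

    def test_eigratio_convention_is_reciprocal(self):
        a = _adj(nx.path_graph(5))
        assert synchronizability(a, "eigratio") == pytest.approx(
            1.0 / synchronizability(a, "ratio")
        )


class TestRobustness:
    def test_complete_graph_closed_form(self):
        n = 6
        a = _adj(nx.complete_graph(n))
        expected = sum(m / n for m in range(1, n + 1)) / n
        assert robustness(a, "targeted") == pytest.approx(expected)
        assert robustness(a, "random", seed=0) == pytest.approx(expected)

    def test_star_targeted_hub_first(self):
        a = _adj(nx.star_graph(5))
        # hub removed first; all remaining fractions are 1/6
        assert robustness(a, "targeted") == pytest.approx((1 + 5 / 6) / 6)

    def test_random_attack_reproducible(self):
        a = _adj(nx.gnm_random_graph(9, 14, seed=1))
        r1 = robustness(a, "random", seed=9)
        r2 = robustness(a, "random", seed=9)
        assert r1 == r2


class TestPhysicalDiagnostics:
    def test_single_edge_distance(self):
        a = np.zeros((8, 8), dtype=bool)
        a[0, 1] = a[1, 0] = True
        pos = np.zeros((8, 3))
        pos[1] = [2.0, 0, 0]
        pos[2:] = np.arange(6)[:, None] * [0, 1.0, 0] + [5, 0, 0]
        assert mean_connection_distance(a, pos) == pytest.approx(2.0)

    def test_complete_graph_equals_mean_pairwise_distance(self, layout12):
        a = ~np.eye(12, dtype=bool)
        d = layout12.distances()
        iu = np.triu_indices(12, 1)
        assert mean_connection_distance(a, layout12) == pytest.approx(
            d[iu].mean()
        )

    def test_longer_edge_increases_mcd(self, layout12):
        d = layout12.distances()
        a = np.zeros((12, 12), dtype=bool)
        order = np.dstack(np.triu_indices(12, 1))[0]
        by_len = order[np.argsort(d[order[:, 0], order[:, 1]])]
        for i, j in by_len[:6]:
            a[i, j] = a[j, i] = True
        before = mean_connection_distance(a, layout12)
        i, j = by_len[-1]
        a[i, j] = a[j, i] = True
        assert mean_connection_distance(a, layout12) > before

    def test_rent_deterministic_and_rewired_higher(self):
        g = nx.grid_2d_graph(12, 12)
        nodes = list(g.nodes)
        idx = {v: i for i, v in enumerate(nodes)}
        a = np.zeros((144, 144), dtype=bool)
        for u, v in g.edges:
            a[idx[u], idx[v]] = a[idx[v], idx[u]] = True
        pos = np.array([[x, y, 0.0] for x, y in nodes])
        p1 = rent_exponent(a, pos, n_boxes=2000, seed=3)
        assert p1 == rent_exponent(a, pos, n_boxes=2000, seed=3)
        wins = 0
        for s in range(10):
            h = nx.double_edge_swap(g.copy(), nswap=150, max_tries=5000, seed=s)
            b = np.zeros_like(a)
            for u, v in h.edges:
                b[idx[u], idx[v]] = b[idx[v], idx[u]] = True
            wins += rent_exponent(b, pos, n_boxes=2000, seed=s) > p1
        assert wins == 10


class TestCostEfficiency:
    def test_identity_curve_gives_zero(self):
        grid = np.array([0.1, 0.2, 0.3])
        res = cost_efficiency(grid.copy(), grid)
        assert res.cost_efficiency == pytest.approx(0.0)

    def test_hand_maximization(self):
        res = cost_efficiency([0.2, 0.5, 0.6], [0.1, 0.3, 0.5])
        assert res.cost_efficiency == pytest.approx(0.2)
        assert res.optimal_cost == pytest.approx(0.3)

    def test_order_free_and_tie_to_smallest_cost(self):
        res = cost_efficiency([0.6, 0.5, 0.2], [0.5, 0.3, 0.1])
        assert res.cost_efficiency == pytest.approx(0.2)
        assert res.optimal_cost == pytest.approx(0.3)

    def test_all_missing_curve(self):
        res = cost_efficiency([np.nan, np.nan], [0.1, 0.2])
        assert np.isnan(res.cost_efficiency)


class TestAllDiagnostics:
    def test_twelve_diagnostics_and_cv_subset(self):
        assert len(DIAGNOSTICS) == 12
        assert len(CV_DIAGNOSTICS) == 10
        assert "hierarchy" not in CV_DIAGNOSTICS
        assert "assortativity" not in CV_DIAGNOSTICS

    def test_empty_graph_all_missing(self, layout12):
        out = all_diagnostics(np.zeros((12, 12), dtype=bool), layout12)
        assert all(np.isnan(v) for v in out.values())

    def test_subset_matches_full_computation(self, layout12, rng):
        a = _adj(nx.gnm_random_graph(12, 26, seed=4))
        full = all_diagnostics(a, layout12, seed=3)
        sub = all_diagnostics(
            a, layout12, seed=3, names=("clustering", "modularity")
        )
        assert sub["clustering"] == full["clustering"]
        assert sub["modularity"] == full["modularity"]

    def test_permutation_equivariance_of_topological_set(self, rng):
        a = _adj(nx.gnm_random_graph(10, 20, seed=6))
        perm = rng.permutation(10)
        b = a[np.ix_(perm, perm)]
        names = (
            "path_length", "clustering", "global_efficiency",
            "local_efficiency", "betweenness", "synchronizability",
        )
        da = all_diagnostics(a, None, seed=0, names=names)
        db = all_diagnostics(b, None, seed=0, names=names)
        for k in names:
            assert da[k] == pytest.approx(db[k], abs=1e-9)
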