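import numpy as np
import pytest

from essnet import (ExpressionMatrix, PPINetwork, ScoreTable,
                    classic_centrality, compute_centrality,
                    edge_clustering_coefficient,
                    expression_weighted_centrality, local_centrality,
                    pearson, rank_candidates)
from conftest import constant_expression, identical_varying_expression
from _oracles import (adjacency_of, brute_betweenness, brute_closeness,
                      brute_degree, brute_eigenvector, brute_lac, brute_nc,
                      brute_pec, brute_wdc, random_connected_graph)


class TestClassicCentrality:
    def test_triangle_symmetry(self, triangle):
        assert all(classic_centrality(triangle, "DC")[v] == 2
                   for v in triangle.nodes)
        assert all(classic_centrality(triangle, "BC")[v] == 0
                   for v in triangle.nodes)
        ec = classic_centrality(triangle, "EC")
        assert np.allclose([ec[v] for v in triangle.nodes], 1 / np.sqrt(3))

    def test_star_betweenness(self, star4):
        bc = classic_centrality(star4, "BC")
        assert bc["c"] == pytest.approx(3.0)  # the C(3,2) leaf pairs
        assert all(bc[v] == 0.0 for v in star4.nodes if v != "c")

    def test_path_closeness(self, path3):
        cc = classic_centrality(path3, "CC")
        assert cc["B"] == pytest.approx(1.0)
        assert cc["A"] == pytest.approx(2 / 3)

    def test_ec_normalized_and_oriented(self, star4):
        ec = classic_centrality(star4, "EC")
        vec = np.array([ec[v] for v in star4.nodes])
        assert np.linalg.norm(vec) == pytest.approx(1.0)
        assert vec.min() >= 0.0

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            classic_centrality(PPINetwork(nodes=(), edges=frozenset()), "DC")


class TestEdgeClusteringCoefficient:
    def test_triangle_edges(self, triangle):
        assert edge_clustering_coefficient(triangle, "A", "B") == 1.0

    def test_path_end_convention(self, path3):
        assert edge_clustering_coefficient(path3, "A", "B") == 0.0

    def test_k4_edges(self, k4):
        # z = 2 common neighbors, min(deg-1) = 2
        assert edge_clustering_coefficient(k4, "A", "B") == 1.0

    def test_non_edge_rejected(self, path3):
        with pytest.raises(ValueError):
            edge_clustering_coefficient(path3, "A", "C")


class TestLocalCentrality:
    def test_k3(self, triangle):
        assert all(local_centrality(triangle, "NC")[v] == pytest.approx(2.0)
                   for v in triangle.nodes)
        assert all(local_centrality(triangle, "LAC")[v] == pytest.approx(1.0)
                   for v in triangle.nodes)

    def test_star_center_is_zero(self, star4):
        assert local_centrality(star4, "NC")["c"] == 0.0
        assert local_centrality(star4, "LAC")["c"] == 0.0

    def test_k4(self, k4):
        assert local_centrality(k4, "NC")["A"] == pytest.approx(3.0)
        assert local_centrality(k4, "LAC")["A"] == pytest.approx(2.0)

    def test_isolated_node_scores_zero(self):
        net = PPINetwork.from_edges([("A", "B")], extra_nodes=["Z"])
        for kind in ("NC", "LAC"):
            assert local_centrality(net, kind)["Z"] == 0.0


class TestPearson:
    def test_identity(self):
        x = np.arange(36, dtype=float)
        assert pearson(x, x) == pytest.approx(1.0)

    def test_negation(self):
        x = np.sin(np.arange(36))
        assert pearson(x, -x) == pytest.approx(-1.0)

    def test_constant_convention(self):
        assert pearson(np.full(36, 3.0), np.arange(36.0)) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            pearson(np.zeros(36), np.zeros(35))


class TestExpressionWeighted:
    def test_k3_identical_profiles(self, triangle):
        expr = identical_varying_expression(triangle.nodes)
        pec = expression_weighted_centrality(triangle, expr, "PeC")
        wdc = expression_weighted_centrality(triangle, expr, "WDC")
        assert all(pec[v] == pytest.approx(2.0) for v in triangle.nodes)
        assert all(wdc[v] == pytest.approx(2.0) for v in triangle.nodes)

    def test_constant_profiles_degenerate(self, k4):
        expr = constant_expression(k4.nodes)
        pec = expression_weighted_centrality(k4, expr, "PeC")
        wdc = expression_weighted_centrality(k4, expr, "WDC")
        nc = local_centrality(k4, "NC")
        assert all(pec[v] == 0.0 for v in k4.nodes)
        for v in k4.nodes:  # WDC reduces to lambda * NC
            assert wdc[v] == pytest.approx(0.5 * nc[v])

    def test_star_center(self, star4):
        expr = identical_varying_expression(star4.nodes)
        pec = expression_weighted_centrality(star4, expr, "PeC")
        wdc = expression_weighted_centrality(star4, expr, "WDC")
        assert pec["c"] == 0.0
        assert wdc["c"] == pytest.approx(0.5 * 3)

    def test_negative_correlations_floored(self, path3):
        up = np.arange(36, dtype=float)
        expr = ExpressionMatrix(rows={"A": up, "B": -up, "C": up})
        pec = expression_weighted_centrality(path3, expr, "PeC")
        assert all(s >= 0.0 for s in pec.scores.values())
        signed = expression_weighted_centrality(path3, expr, "WDC",
                                                clip_negative=False)
        assert min(signed.scores.values()) < 0.0


class TestRankCandidates:
    def test_descending(self):
        table = ScoreTable(scores={"A": 3, "B": 1, "C": 2}, method_name="t")
        assert rank_candidates(table, 2) == ["A", "C"]

    def test_tie_breaks_alphabetically(self):
        table = ScoreTable(scores={"B": 1, "A": 1, "C": 1}, method_name="t")
        assert rank_candidates(table, 2) == ["A", "B"]

    def test_matches_full_sort(self):
        rng = np.random.default_rng(8)
        table = ScoreTable(scores={f"P{i:03d}": float(rng.integers(0, 20))
                                   for i in range(100)}, method_name="t")
        expected = sorted(table.scores,
                          key=lambda v: (-table.scores[v], v))[:10]
        assert rank_candidates(table, 10) == expected

    def test_k_too_large(self):
        table = ScoreTable(scores={"A": 1.0}, method_name="t")
        with pytest.raises(ValueError):
            rank_candidates(table, 2)


class TestBruteForceEquivalence:
    """All eight indices vs naive oracles on random small graphs."""

    @pytest.mark.parametrize("seed", range(25))
    def test_all_methods_small_graphs(self, seed):
        rng = np.random.default_rng(1000 + seed)
        nodes, edges = random_connected_graph(rng)
        net = PPINetwork.from_edges(edges)
        adj = adjacency_of(net.nodes, net.edges)
        expr = ExpressionMatrix(
            rows={v: rng.normal(size=36) for v in net.nodes})
        oracle = {
            "DC": brute_degree(adj),
            "BC": brute_betweenness(adj),
            "CC": brute_closeness(adj),
            "EC": brute_eigenvector(adj),
            "NC": brute_nc(adj),
            "LAC": brute_lac(adj),
            "PeC": brute_pec(adj, expr.rows),
            "WDC": brute_wdc(adj, expr.rows),
        }
        for kind, expected in oracle.items():
            got = compute_centrality(net, kind, expr=expr)
            for v in net.nodes:
                assert got[v] == pytest.approx(expected[v], abs=1e-8), \
                    (kind, v, sorted(edges))


class TestInvariants:
    def test_nc_bounded_by_degree(self):
        rng = np.random.default_rng(17)
        nodes, edges = random_connected_graph(rng, min_n=6, max_n=7)
        net = PPINetwork.from_edges(edges)
        nc = local_centrality(net, "NC")
        lac = local_centrality(net, "LAC")
        pec = expression_weighted_centrality(
            net, ExpressionMatrix(rows={v: rng.normal(size=36)
                                        for v in net.nodes}), "PeC")
        for v in net.nodes:
            assert nc[v] <= net.degree(v) + 1e-12
            if net.degree(v) >= 1:
                assert lac[v] <= net.degree(v) - 1 + 1e-12
            assert pec[v] <= nc[v] + 1e-12

    @pytest.mark.parametrize("kind", ["DC", "BC", "CC", "EC", "NC", "LAC",
                                      "PeC", "WDC"])
    def test_relabeling_invariance(self, kind):
        rng = np.random.default_rng(23)
        nodes, edges = random_connected_graph(rng, min_n=6, max_n=7)
        net = PPINetwork.from_edges(edges)
        expr_rows = {v: rng.normal(size=36) for v in net.nodes}
        mapping = {v: f"x{ord(v[0]) + i}{v}" for i, v in enumerate(net.nodes)}
        relabeled = PPINetwork.from_edges(
            [(mapping[u], mapping[v]) for u, v in edges])
        got = compute_centrality(net, kind,
                                 expr=ExpressionMatrix(rows=dict(expr_rows)))
        got2 = compute_centrality(
            relabeled, kind,
            expr=ExpressionMatrix(rows={mapping[v]: r
                                        for v, r in expr_rows.items()}))
        for v in net.nodes:
            assert got[v] == pytest.approx(got2[mapping[v]], abs=1e-9)
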