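import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from essnet import (EmbeddingTable, PPINetwork, SkipGramConfig, WalkConfig,
                    embed_network, generate_walks, train_embedding,
                    transition_distribution)
from _oracles import adjacency_of, random_connected_graph


def path_graph(n):
    return PPINetwork.from_edges(
        [(f"n{i}", f"n{i+1}") for i in range(n - 1)])


class TestTransitionDistribution:
    def test_uniform_when_p_q_one(self, k4):
        dist = transition_distribution(k4, "A", "B", 1.0, 1.0)
        assert set(dist) == {"A", "C", "D"}
        assert all(abs(p - 1 / 3) < 1e-12 for p in dist.values())

    def test_biased_on_path(self, path3):
        # prev=A, cur=B: back to A weight 1/p=0.5, on to C weight 1/q=2
        dist = transition_distribution(path3, "A", "B", 2.0, 0.5)
        assert dist["A"] == pytest.approx(0.2)
        assert dist["C"] == pytest.approx(0.8)

    @given(seed=st.integers(0, 500), p=st.floats(0.25, 4.0),
           q=st.floats(0.25, 4.0))
    @settings(max_examples=40, deadline=None)
    def test_proper_distribution(self, seed, p, q):
        rng = np.random.default_rng(seed)
        nodes, edges = random_connected_graph(rng)
        net = PPINetwork.from_edges(edges)
        u, v = sorted(edges)[int(rng.integers(len(edges)))]
        dist = transition_distribution(net, u, v, p, q)
        assert set(dist) == set(net.neighbors(v))
        assert min(dist.values()) >= 0.0
        assert sum(dist.values()) == pytest.approx(1.0, abs=1e-12)

    def test_non_adjacent_rejected(self, path3):
        with pytest.raises(ValueError):
            transition_distribution(path3, "A", "C", 1.0, 1.0)


class TestGenerateWalks:
    @pytest.mark.parametrize("p,q", [(1.0, 1.0), (2.0, 0.5)])
    def test_walk_count_and_adjacency(self, p, q):
        net = path_graph(5)
        cfg = WalkConfig(p=p, q=q, walk_length=10, walks_per_node=2, seed=3)
        corpus = generate_walks(net, cfg)
        assert len(corpus) == 10
        for walk in corpus.walks:
            for a, b in zip(walk, walk[1:]):
                assert net.has_edge(a, b)

    def test_walks_start_everywhere(self):
        net = path_graph(4)
        cfg = WalkConfig(walk_length=5, walks_per_node=3, seed=0)
        starts = [w[0] for w in generate_walks(net, cfg).walks]
        assert all(starts.count(v) == 3 for v in net.nodes)

    def test_single_edge_alternates(self):
        net = PPINetwork.from_edges([("A", "B")])
        cfg = WalkConfig(walk_length=4, walks_per_node=1, seed=1)
        for walk in generate_walks(net, cfg).walks:
            assert len(walk) == 4
            assert all(a != b for a, b in zip(walk, walk[1:]))

    @pytest.mark.parametrize("p,q", [(1.0, 1.0), (0.5, 2.0)])
    def test_deterministic(self, p, q):
        net = path_graph(6)
        cfg = WalkConfig(p=p, q=q, walk_length=8, walks_per_node=2, seed=9)
        assert generate_walks(net, cfg).walks == generate_walks(net, cfg).walks

    def test_isolated_start_truncates(self):
        net = PPINetwork.from_edges([("A", "B")], extra_nodes=["Z"])
        cfg = WalkConfig(walk_length=5, walks_per_node=1, seed=0)
        walks = generate_walks(net, cfg).walks
        assert ["Z"] in walks

    def test_return_bias_is_visible(self):
        # very low p => immediate backtracking dominates on a path interior
        net = path_graph(9)
        high_return = WalkConfig(p=0.01, q=1.0, walk_length=30,
                                 walks_per_node=4, seed=5)
        explore = WalkConfig(p=100.0, q=1.0, walk_length=30,
                             walks_per_node=4, seed=5)

        def mean_unique(cfg):
            return np.mean([len(set(w))
                            for w in generate_walks(net, cfg).walks])

        assert mean_unique(high_return) < mean_unique(explore)


class TestTrainEmbedding:
    def test_vector_shape_contract(self):
        net = path_graph(6)
        corpus = generate_walks(net, WalkConfig(walk_length=10,
                                                walks_per_node=4, seed=0))
        table = train_embedding(corpus, cfg=SkipGramConfig(epochs=1, seed=0))
        assert table.dimension == 64
        assert all(v.shape == (64,) for v in table.vectors.values())

    def test_deterministic(self):
        net = path_graph(8)
        corpus = generate_walks(net, WalkConfig(walk_length=12,
                                                walks_per_node=3, seed=2))
        cfg = SkipGramConfig(epochs=2, seed=7)
        t1 = train_embedding(corpus, cfg=cfg)
        t2 = train_embedding(corpus, cfg=cfg)
        for key in t1.vectors:
            np.testing.assert_array_equal(t1[key], t2[key])

    def test_planted_partition_communities_separate(self):
        rng = np.random.default_rng(11)
        edges = []
        for block, offset in ((0, 0), (1, 20)):
            for i in range(20):
                for j in range(i + 1, 20):
                    if rng.random() < 0.5:
                        edges.append((f"v{offset+i}", f"v{offset+j}"))
        for i in range(20):
            for j in range(20):
                if rng.random() < 0.02:
                    edges.append((f"v{i}", f"v{20+j}"))
        net = PPINetwork.from_edges(edges)
        corpus = generate_walks(net, WalkConfig(walk_length=20,
                                                walks_per_node=8, seed=1))
        table = train_embedding(
            corpus, cfg=SkipGramConfig(window=5, epochs=3, seed=1))

        def cos(a, b):
            return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))

        ids = sorted(net.nodes)
        a = [v for v in ids if int(v[1:]) < 20]
        b = [v for v in ids if int(v[1:]) >= 20]
        within = np.mean([cos(table[x], table[y])
                          for i, x in enumerate(a) for y in a[i + 1:]])
        across = np.mean([cos(table[x], table[y]) for x in a for y in b])
        assert within > across

    def test_bad_dim(self):
        corpus = generate_walks(path_graph(3),
                                WalkConfig(walk_length=4, walks_per_node=1,
                                           seed=0))
        with pytest.raises(ValueError):
            train_embedding(corpus, dim=0)


class TestEmbedNetwork:
    def test_empty_network(self):
        table = embed_network(PPINetwork(nodes=(), edges=frozenset()))
        assert len(table) == 0

    def test_scale_free_coverage_and_serialisation(self, tmp_path):
        import networkx as nx

        g = nx.barabasi_albert_graph(30, 2, seed=4)
        net = PPINetwork.from_edges((f"p{u}", f"p{v}") for u, v in g.edges())
        cfg = (WalkConfig(walk_length=10, walks_per_node=3, seed=0),
               SkipGramConfig(window=3, epochs=1, seed=0))
        t1 = embed_network(net, *cfg)
        assert len(t1) == net.n_nodes
        t1.to_tsv(tmp_path / "a.tsv")
        embed_network(net, *cfg).to_tsv(tmp_path / "b.tsv")
        assert (tmp_path / "a.tsv").read_bytes() == \
            (tmp_path / "b.tsv").read_bytes()

    def test_isolated_nodes_get_zero_vectors(self):
        net = PPINetwork.from_edges([("A", "B")], extra_nodes=["Z"])
        table = embed_network(
            net, WalkConfig(walk_length=4, walks_per_node=2, seed=0),
            SkipGramConfig(window=2, epochs=1, seed=0))
        # Z occurs in walks only as a singleton start; it still gets a vector
        assert "Z" in table.vectors

    def test_cycle_is_approximately_exchangeable(self):
        # on a vertex-transitive graph every node sees the same geometry:
        # per-node mean distance to its two ring neighbors should vary
        # little relative to the overall pairwise distance scale
        n = 12
        net = PPINetwork.from_edges(
            [(f"c{i:02d}", f"c{(i+1) % n:02d}") for i in range(n)])
        table = embed_network(
            net, WalkConfig(walk_length=20, walks_per_node=10, seed=3),
            SkipGramConfig(window=4, epochs=4, seed=3))
        ids = sorted(net.nodes)
        vecs = {v: table[v] for v in ids}
        ring = [float(np.linalg.norm(vecs[f"c{i:02d}"]
                                     - vecs[f"c{(i+1) % n:02d}"]))
                for i in range(n)]
        all_pairs = [float(np.linalg.norm(vecs[x] - vecs[y]))
                     for i, x in enumerate(ids) for y in ids[i + 1:]]
        assert np.std(ring) < np.mean(all_pairs)


class TestEmbeddingTable:
    def test_tsv_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        table = EmbeddingTable(vectors={f"P{i}": rng.normal(size=64)
                                        for i in range(3)})
        table.to_tsv(tmp_path / "t.tsv")
        again = EmbeddingTable.from_tsv(tmp_path / "t.tsv")
        for key in table.vectors:
            np.testing.assert_array_equal(table[key], again[key])

    def test_word2vec_header(self, tmp_path):
        table = EmbeddingTable(vectors={"A": np.zeros(64)})
        table.to_word2vec(tmp_path / "w.txt")
        assert (tmp_path / "w.txt").read_text().splitlines()[0] == "1 64"

    def test_as_matrix_zero_fills_missing(self):
        table = EmbeddingTable(vectors={"A": np.ones(64)})
        mat = table.as_matrix(["A", "B"])
        assert mat.shape == (2, 64)
        assert np.all(mat[1] == 0.0)
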