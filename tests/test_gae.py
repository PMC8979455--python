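"""Edge splitting, adjacency normalization and the graph autoencoder."""
import numpy as np
import pytest

from conftest import make_er_graph, make_planted_graph, make_two_cliques
from copulagcn.gae import (
    GCNParams,
    Embedding,
    gcn_encode,
    init_weights,
    inner_product_decode,
    normalize_adjacency,
    split_edges,
    train_gae,
)
from copulagcn.graph import CellGraph


class TestSplitEdges:
    def test_partition_ratios_and_determinism(self):
        g = make_er_graph(n=60, p=0.12, seed=1)
        n_edges = len(g.edges)
        s1 = split_edges(g, seed=3)
        s2 = split_edges(g, seed=3)
        assert s1.train_edges == s2.train_edges and s1.val_neg == s2.val_neg
        parts = [set(s1.train_edges), set(s1.val_edges), set(s1.test_edges)]
        assert parts[0] | parts[1] | parts[2] == g.edges
        assert not (parts[0] & parts[1] or parts[0] & parts[2] or parts[1] & parts[2])
        assert len(s1.val_edges) == round(0.1 * n_edges)
        assert len(s1.test_edges) == round(0.1 * n_edges)
        assert len(s1.val_neg) == len(s1.val_edges)
        assert len(s1.test_neg) == len(s1.test_edges)

    def test_hundred_edges_split_80_10_10(self):
        # build a graph with exactly 100 edges
        edges = set()
        i = 0
        nodes = 40
        for a in range(nodes):
            for b in range(a + 1, nodes):
                if len(edges) < 100:
                    edges.add((a, b))
        g = CellGraph(n_nodes=nodes, edges=edges, ranked_lists=[])
        s = split_edges(g, seed=0)
        assert (len(s.train_edges), len(s.val_edges), len(s.test_edges)) == (80, 10, 10)

    def test_negatives_are_nonedges(self):
        g = make_er_graph(n=50, p=0.1, seed=2)
        s = split_edges(g, seed=1)
        for e in s.val_neg + s.test_neg:
            assert e not in g.edges and e[0] != e[1]

    def test_too_few_edges(self):
        g = CellGraph(n_nodes=5, edges={(0, 1), (2, 3)}, ranked_lists=[])
        with pytest.raises(ValueError, match="degenerate"):
            split_edges(g)


class TestNormalizeAdjacency:
    def test_two_nodes_one_edge(self):
        g = CellGraph(n_nodes=2, edges={(0, 1)}, ranked_lists=[])
        np.testing.assert_allclose(normalize_adjacency(g), [[0.5, 0.5], [0.5, 0.5]])

    def test_single_node_self_loop(self):
        g = CellGraph(n_nodes=1, edges=set(), ranked_lists=[])
        np.testing.assert_allclose(normalize_adjacency(g), [[1.0]])

    def test_regular_graph_row_sums(self):
        # cycle graph: every node degree 2 -> rows sum to exactly 1
        n = 8
        edges = {(i, (i + 1) % n) if i + 1 < n else (0, n - 1) for i in range(n)}
        edges = {(min(a, b), max(a, b)) for a, b in edges}
        g = CellGraph(n_nodes=n, edges=edges, ranked_lists=[])
        a = normalize_adjacency(g)
        np.testing.assert_allclose(a.sum(axis=1), 1.0)
        np.testing.assert_allclose(a, a.T)

    def test_spectrum_in_unit_interval(self):
        for seed, n in [(0, 50), (1, 120), (2, 200)]:
            g = make_er_graph(n=n, p=0.05, seed=seed)
            eig = np.linalg.eigvalsh(normalize_adjacency(g))
            assert eig.min() >= -1 - 1e-9 and eig.max() <= 1 + 1e-9


class TestEncoderDecoder:
    def test_zero_weights_zero_embedding(self):
        g = make_er_graph(n=20, p=0.2, seed=0)
        a = normalize_adjacency(g)
        params = GCNParams(layer_dims=(8, 6, 4))
        w = [np.zeros((20, 8)), np.zeros((8, 6)), np.zeros((6, 4))]
        z = gcn_encode(a, params, w).Z
        assert np.all(z == 0)

    def test_permutation_equivariance(self):
        g = make_er_graph(n=15, p=0.25, seed=1)
        a = normalize_adjacency(g)
        params = GCNParams(layer_dims=(8, 6, 4), seed=0)
        rng = np.random.default_rng(0)
        w = init_weights(15, params, rng)
        z = gcn_encode(a, params, w).Z
        perm = np.random.default_rng(1).permutation(15)
        ap = a[np.ix_(perm, perm)]
        wp = [w[0][perm], w[1], w[2]]
        zp = gcn_encode(ap, params, wp).Z
        np.testing.assert_allclose(zp, z[perm], atol=1e-5)

    def test_identical_neighborhoods_identical_rows(self):
        # 4-cycle: nodes 0 and 2 share the neighbour set {1, 3}; with equal
        # node features they must embed identically
        g = CellGraph(n_nodes=4, edges={(0, 1), (1, 2), (2, 3), (0, 3)}, ranked_lists=[])
        a = normalize_adjacency(g)
        params = GCNParams(layer_dims=(5, 4, 3))
        rng = np.random.default_rng(2)
        X = np.ones((4, 2))
        w = [rng.normal(size=(2, 5)), rng.normal(size=(5, 4)), rng.normal(size=(4, 3))]
        z = gcn_encode(a, params, w, X=X).Z
        np.testing.assert_allclose(z[0], z[2], atol=1e-12)
        np.testing.assert_allclose(z[1], z[3], atol=1e-12)

    def test_decoder_values_and_symmetry(self):
        z = np.zeros((3, 4))
        z[1] = np.sqrt(np.log(3) / 4)  # ||z1||^2 = ln 3
        z[2] = -z[1]
        emb = Embedding(Z=z, cell_ids=["a", "b", "c"])
        assert inner_product_decode(emb, 0, 1) == pytest.approx(0.5)  # sigmoid(0)
        assert inner_product_decode(emb, 1, 1) == pytest.approx(0.75)  # sigmoid(ln 3)
        assert inner_product_decode(emb, 1, 2) == pytest.approx(0.25)
        assert inner_product_decode(emb, 1, 2) == inner_product_decode(emb, 2, 1)


class TestTraining:
    def test_two_cliques_high_roc(self):
        """Perfectly separable planted structure: the trained model recovers
        held-out within-clique edges (median test ROC over 10 seeds)."""
        rocs = []
        for seed in range(10):
            g = make_two_cliques(30)
            split = split_edges(g, seed=seed)
            _, rep, _ = train_gae(g, GCNParams(seed=seed), split)
            rocs.append(rep.test_roc)
        assert np.median(rocs) >= 0.9

    def test_untrained_is_chance_on_unstructured_graph(self):
        """With no graph structure (Erdos-Renyi), an untrained encoder cannot
        rank held-out edges above non-edges."""
        rocs = []
        for seed in range(7):
            g = make_er_graph(n=120, p=0.08, seed=seed)
            split = split_edges(g, seed=seed)
            _, rep, _ = train_gae(g, GCNParams(epochs=0, seed=seed), split)
            rocs.append(rep.test_roc)
        assert abs(np.median(rocs) - 0.5) < 0.1

    def test_training_beats_untrained(self):
        # partially-random structure: training must add signal over the
        # untrained (graph-smoothing only) encoder, median over 5 seeds
        diffs = []
        for seed in range(5):
            g = make_planted_graph(n=150, seed=seed)
            split = split_edges(g, seed=seed)
            _, rep0, _ = train_gae(g, GCNParams(epochs=0, seed=seed), split)
            _, rep, _ = train_gae(g, GCNParams(seed=seed), split)
            diffs.append(rep.test_roc - rep0.test_roc)
        assert np.median(diffs) > 0

    def test_loss_soft_monotone(self):
        g = make_two_cliques(30)
        split = split_edges(g, seed=1)
        _, rep, _ = train_gae(g, GCNParams(seed=1), split)
        hist = np.array(rep.loss_history)
        frac_decreasing = np.mean(np.diff(hist) <= 0)
        assert frac_decreasing >= 0.8

    def test_bitwise_deterministic(self):
        g = make_planted_graph(n=80, seed=4)
        split = split_edges(g, seed=4)
        emb1, rep1, _ = train_gae(g, GCNParams(seed=7), split)
        emb2, rep2, _ = train_gae(g, GCNParams(seed=7), split)
        assert rep1.loss_history == rep2.loss_history
        np.testing.assert_array_equal(emb1.Z, emb2.Z)

    def test_embedding_dim_and_finiteness(self):
        g = make_two_cliques(20)
        split = split_edges(g, seed=0)
        params = GCNParams(layer_dims=(32, 16, 16), seed=0)
        emb, rep, weights = train_gae(g, params, split)
        assert emb.Z.shape == (40, 16)
        assert np.all(np.isfinite(emb.Z))
        assert weights[0].shape == (40, 32)
        for v in (rep.val_roc, rep.val_ap, rep.test_roc, rep.test_ap):
            assert 0.0 <= v <= 1.0
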