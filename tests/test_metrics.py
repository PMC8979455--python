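"""Clustering metrics, topology KL, distance preservation, marker calling."""
import numpy as np
import pytest
from scipy import stats

from copulagcn.metrics import (
    LabelVector,
    ari,
    distance_preservation_tau,
    find_markers,
    kl_from_edge_sets,
    kmeans_cluster,
    silhouette,
    topology_kl,
)
from copulagcn.preprocess import NormMatrix


def norm_from(values):
    values = np.asarray(values, float)
    n, g = values.shape
    return NormMatrix(values, [f"c{i}" for i in range(n)], [f"g{j}" for j in range(g)], {})


def two_blobs(n_per=30, sep=8.0, d=5, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(0, 1, size=(n_per, d))
    b = rng.normal(sep, 1, size=(n_per, d))
    X = np.vstack([a, b])
    labels = np.array([0] * n_per + [1] * n_per)
    return X, labels


class TestKmeans:
    def test_recovers_planted_blobs(self):
        X, truth = two_blobs()
        lab = kmeans_cluster(X, K=2, seed=0)
        assert ari(lab.labels, truth) == 1.0

    def test_k_equals_n_and_determinism(self):
        X = np.random.default_rng(0).normal(size=(8, 3))
        lab = kmeans_cluster(X, K=8, seed=1)
        assert len(set(lab.labels)) == 8
        lab2 = kmeans_cluster(X, K=8, seed=1)
        np.testing.assert_array_equal(lab.labels, lab2.labels)
        with pytest.raises(ValueError):
            kmeans_cluster(X, K=9, seed=0)


class TestAri:
    def test_identity_and_relabel_invariance(self):
        a = np.array([0, 0, 1, 1, 2, 2])
        assert ari(a, a) == 1.0
        assert ari(a, 2 - a) == 1.0

    def test_matches_pair_counting_oracle(self):
        # contingency [[2,1],[1,2]] on 6 items
        a = np.array([0, 0, 0, 1, 1, 1])
        b = np.array([0, 0, 1, 0, 1, 1])

        def pair_ari(x, y):
            n = len(x)
            s00 = s01 = s10 = s11 = 0
            for i in range(n):
                for j in range(i + 1, n):
                    sx, sy = x[i] == x[j], y[i] == y[j]
                    s11 += sx and sy
                    s00 += (not sx) and (not sy)
                    s10 += sx and not sy
                    s01 += (not sx) and sy
            idx = s11
            total = s11 + s10 + s01 + s00
            exp = (s11 + s10) * (s11 + s01) / total
            mx = 0.5 * ((s11 + s10) + (s11 + s01))
            return (idx - exp) / (mx - exp)

        assert ari(a, b) == pytest.approx(pair_ari(a, b))

    def test_null_expectation_near_zero(self):
        rng = np.random.default_rng(0)
        vals = [
            ari(rng.integers(0, 3, 60), rng.integers(0, 3, 60)) for _ in range(200)
        ]
        assert abs(np.mean(vals)) < 0.02

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            ari(np.zeros(3, int), np.zeros(4, int))


class TestSilhouette:
    def test_separated_blobs_near_one(self):
        X, truth = two_blobs(sep=100.0)
        assert silhouette(X, truth) > 0.95

    def test_random_labels_near_zero(self):
        rng = np.random.default_rng(1)
        vals = []
        for seed in range(10):
            X = np.random.default_rng(seed).normal(size=(60, 4))
            vals.append(silhouette(X, rng.integers(0, 2, 60)))
        assert abs(np.median(vals)) < 0.1

    def test_four_point_hand_computed(self):
        # 1-D points 0, 1 (cluster 0) and 10, 11 (cluster 1):
        # s(0) = (10.5-1)/10.5, s(1) = (9.5-1)/9.5, symmetric on the right
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        lab = np.array([0, 0, 1, 1])
        expected = (2 * (9.5 / 10.5) + 2 * (8.5 / 9.5)) / 4
        assert silhouette(X, lab) == pytest.approx(expected)


class TestTopologyKL:
    def test_identical_graphs_zero(self):
        X, _ = two_blobs(seed=3)
        rep = topology_kl(X, X.copy(), k_ref=5)
        assert rep.kl == 0.0
        # a rigid transform preserves the kNN graph exactly
        rep2 = topology_kl(X, 2.0 * X + 7.0, k_ref=5)
        assert rep2.kl == 0.0

    def test_hand_enumerated_four_nodes(self):
        # E_FC has 6 pairs; reference {(0,1)} vs predicted {(2,3)}:
        # both mismatches contribute log(1/eps) under the exact convention
        eps = 0.01
        rep = kl_from_edge_sets(4, {(0, 1)}, {(2, 3)}, epsilon=eps)
        assert rep.kl == pytest.approx(2 * np.log(1 / eps))
        # fully-smoothed convention adds log(1/(1-eps)) for the 4 agreeing pairs
        rep_all = kl_from_edge_sets(4, {(0, 1)}, {(2, 3)}, epsilon=eps, smoothing="all")
        assert rep_all.kl == pytest.approx(2 * np.log(1 / eps) + 4 * np.log(1 / (1 - eps)))

    def test_monotone_in_overlap(self):
        ref = {(0, 1), (1, 2), (2, 3), (3, 4)}
        base = {(0, 2), (1, 3), (2, 4), (0, 4)}
        kls = []
        overlap_steps = [0, 1, 2, 3, 4]
        for k in overlap_steps:
            emb = set(list(ref)[:k]) | set(list(base)[: 4 - k])
            kls.append(kl_from_edge_sets(6, ref, emb).kl)
        assert all(a > b for a, b in zip(kls, kls[1:]))
        assert kls[-1] == 0.0

    def test_nonnegative_and_subsample_unbiased(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 6))
        Z = rng.normal(size=(40, 3))
        full = topology_kl(X, Z, k_ref=4)
        assert full.kl >= 0
        subs = [
            topology_kl(X, Z, k_ref=4, negative_subsample=300, seed=s).kl
            for s in range(20)
        ]
        assert np.mean(subs) == pytest.approx(full.kl, rel=0.15)

    def test_epsilon_validation(self):
        X = np.random.default_rng(0).normal(size=(10, 3))
        with pytest.raises(ValueError):
            topology_kl(X, X, epsilon=0.7)


class TestDistancePreservation:
    def test_rigid_transform_exact_one(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 6))
        # rotation + uniform scaling + translation
        q, _ = np.linalg.qr(rng.normal(size=(6, 6)))
        Z = 3.5 * X @ q + 2.0
        assert distance_preservation_tau(X, Z) == 1.0

    def test_unrelated_embedding_near_zero(self):
        taus = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(40, 8))
            Z = rng.normal(size=(40, 8))
            taus.append(distance_preservation_tau(X, Z))
        assert abs(np.median(taus)) < 0.05

    def test_four_points_brute_force(self):
        X = np.array([[0.0, 0], [1, 0], [0, 2], [3, 3]])
        Z = np.array([[0.0], [2.0], [1.0], [7.0]])
        from scipy.spatial.distance import pdist

        from copulagcn.copula import kendall_tau_brute

        expected = kendall_tau_brute(pdist(X), pdist(Z))
        assert distance_preservation_tau(X, Z) == pytest.approx(expected)


class TestFindMarkers:
    def make_norm(self, vals):
        return norm_from(vals)

    def test_exclusive_gene_top_ranked(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 1, size=(30, 20))
        vals[:15, 7] += 5.0  # gene 7 high only in cluster 0
        labels = np.array([0] * 15 + [1] * 15)
        table = find_markers(self.make_norm(vals), labels)
        c0 = table[table.cluster == 0]
        assert c0.iloc[0]["gene"] == "g7"
        assert c0.iloc[0]["pvalue"] < 0.05
        assert c0.iloc[0]["statistic"] > 0

    def test_exact_small_sample_p(self):
        # 3 vs 3, fully separated, no ties: U at its extreme (9) and the
        # exact two-sided p over the 20 arrangements = 2/20 = 0.1
        vals = np.array([[7.0], [8.0], [9.0], [1.0], [2.0], [3.0]])
        labels = np.array([0, 0, 0, 1, 1, 1])
        table = find_markers(self.make_norm(vals), labels, alpha=0.15)
        row = table[table.cluster == 0].iloc[0]
        assert row["pvalue"] == pytest.approx(0.1)
        assert row["statistic"] > 0
        # cross-check against scipy's exact test
        ref = stats.mannwhitneyu(vals[:3, 0], vals[3:, 0], alternative="two-sided")
        assert ref.pvalue == pytest.approx(0.1)

    def test_null_type_one_error(self):
        """Identically distributed genes are kept at alpha=0.05 in <= 6% of
        cases (200-rep simulation)."""
        rng = np.random.default_rng(11)
        kept = total = 0
        labels = np.array([0] * 25 + [1] * 25)
        for _ in range(200):
            vals = rng.uniform(size=(50, 10))
            table = find_markers(self.make_norm(vals), labels, alpha=0.05)
            kept += len(table) / 2  # two clusters report the same genes
            total += 10
        assert kept / total <= 0.06

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(4)
        vals = rng.uniform(size=(60, 300))
        labels = np.array([0] * 30 + [1] * 30)
        table = find_markers(self.make_norm(vals), labels, alpha=1.01, top_n=300)
        pv = table[table.cluster == 0]["pvalue"].to_numpy()
        assert len(pv) == 300
        assert stats.kstest(pv, "uniform").pvalue > 0.01

    def test_bh_adjustment_more_conservative(self):
        rng = np.random.default_rng(6)
        vals = rng.uniform(size=(40, 50))
        labels = np.array([0] * 20 + [1] * 20)
        raw = find_markers(self.make_norm(vals), labels, alpha=0.5)
        adj = find_markers(self.make_norm(vals), labels, alpha=0.5, adjust="bh")
        assert len(adj) <= len(raw)

    def test_singleton_cluster_skipped(self):
        vals = np.random.default_rng(0).uniform(size=(10, 5))
        labels = np.array([0] * 9 + [1])
        with pytest.warns(UserWarning, match="fewer than 2"):
            table = find_markers(norm_from(vals), labels)
        assert set(table.cluster) <= {0}
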