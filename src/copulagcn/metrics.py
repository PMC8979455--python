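"""Clustering of the embedding and the evaluation suite.

Covers k-means clustering with ARI / average silhouette width, the
topology-preservation KL score (does the kNN graph of the embedding match
the kNN graph of the high-dimensional data?), the Kendall correlation
between high- and low-dimensional cell-cell distance matrices, and
per-cluster Wilcoxon rank-sum marker detection.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score, silhouette_score

from .gae import Embedding
from .preprocess import NormMatrix


@dataclass
class LabelVector:
    labels: np.ndarray
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1 or len(self.labels) != len(self.cell_ids):
            raise ValueError("labels must be one integer per cell")

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.labels))


@dataclass
class TopologyReport:
    kl: float
    n_ref_edges: int
    k_ref: int
    epsilon: float
    negative_subsample: int | str
    n_mismatched: int


def _as_array(z) -> np.ndarray:
    return z.Z if isinstance(z, Embedding) else np.asarray(z, dtype=float)


def kmeans_cluster(
    Z: Embedding | np.ndarray, K: int, seed: int = 0, restarts: int = 10
) -> LabelVector:
    """Best-inertia k-means++ labeling over ``restarts`` initializations."""
    z = _as_array(Z)
    if K < 2 or K > z.shape[0]:
        raise ValueError(f"K={K} must be in [2, n_cells={z.shape[0]}]")
    km = KMeans(n_clusters=K, n_init=restarts, random_state=seed)
    labels = km.fit_predict(z)
    ids = Z.cell_ids if isinstance(Z, Embedding) else [f"cell{i}" for i in range(z.shape[0])]
    return LabelVector(labels=labels, cell_ids=list(ids))


def ari(a: LabelVector | np.ndarray, b: LabelVector | np.ndarray) -> float:
    """Adjusted Rand index between two partitions."""
    la = a.labels if isinstance(a, LabelVector) else np.asarray(a)
    lb = b.labels if isinstance(b, LabelVector) else np.asarray(b)
    if len(la) != len(lb):
        raise ValueError("label vectors must have equal length")
    return float(adjusted_rand_score(la, lb))


def silhouette(Z: Embedding | np.ndarray, labels: LabelVector | np.ndarray) -> float:
    """Average silhouette width with Euclidean distances.

    Cells in singleton clusters score 0 (scikit-learn's convention)."""
    z = _as_array(Z)
    lab = labels.labels if isinstance(labels, LabelVector) else np.asarray(labels)
    if len(np.unique(lab)) < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    counts = np.bincount(lab)
    if np.any(counts[counts > 0] == 1):
        warnings.warn("singleton cluster(s): affected cells scored 0", stacklevel=2)
    return float(silhouette_score(z, lab, metric="euclidean"))


def _knn_edge_set(x: np.ndarray, k: int) -> set[tuple[int, int]]:
    """Undirected union of each point's directed k nearest (Euclidean,
    ties by ascending index) — same construction rule as the cell graph."""
    n = x.shape[0]
    d2 = np.sum((x[:, None, :] - x[None, :, :]) ** 2, axis=-1)
    np.fill_diagonal(d2, np.inf)
    edges: set[tuple[int, int]] = set()
    idx = np.arange(n)
    for i in range(n):
        order = np.lexsort((idx, d2[i]))[:k]
        for j in order:
            edges.add((min(i, int(j)), max(i, int(j))))
    return edges


def topology_kl(
    X_highdim: np.ndarray,
    Z: Embedding | np.ndarray,
    k_ref: int = 5,
    epsilon: float = 1e-4,
    negative_subsample: int | str = "all",
    seed: int = 0,
    smoothing: str = "exact",
) -> TopologyReport:
    """KL divergence of the embedding's edge-probability model from the
    high-dimensional kNN reference.

    The reference distribution P puts p_e = 1 on edges of the kNN graph of
    ``X_highdim`` and 0 elsewhere over the complete pair set.  Q is the
    epsilon-smoothed indicator of the kNN graph built on ``Z`` with the same
    k, under the exact-agreement convention: wherever the two indicators
    agree, q_e = p_e and the pair contributes nothing, so KL(P, P) = 0 and
    each disagreeing pair contributes log(1/epsilon).  With an integer
    ``negative_subsample``, non-reference pairs are uniformly subsampled and
    their contribution rescaled, an unbiased estimate for large graphs.
    """
    x = np.asarray(X_highdim, dtype=float)
    z = _as_array(Z)
    if x.shape[0] != z.shape[0]:
        raise ValueError("X_highdim and Z must have the same number of cells")
    ref = _knn_edge_set(x, k_ref)
    emb = _knn_edge_set(z, k_ref)
    return kl_from_edge_sets(
        x.shape[0], ref, emb, k_ref=k_ref, epsilon=epsilon,
        negative_subsample=negative_subsample, seed=seed, smoothing=smoothing,
    )


def kl_from_edge_sets(
    n: int,
    ref: set[tuple[int, int]],
    emb: set[tuple[int, int]],
    k_ref: int = 5,
    epsilon: float = 1e-4,
    negative_subsample: int | str = "all",
    seed: int = 0,
    smoothing: str = "exact",
) -> TopologyReport:
    """KL of the smoothed edge-indicator Q from the 0/1 reference P.

    ``smoothing="exact"`` (default): agreeing pairs contribute 0 (q_e = p_e
    where the indicators agree), each disagreeing pair log(1/epsilon), so
    KL(P, P) = 0.  ``smoothing="all"``: q_e = 1-epsilon on predicted edges
    and epsilon elsewhere everywhere, so even agreeing pairs contribute
    log(1/(1-epsilon)) — the fully-smoothed reading of the same model.
    """
    if not 0 < epsilon < 0.5:
        raise ValueError("epsilon must lie in (0, 0.5)")
    if smoothing not in ("exact", "all"):
        raise ValueError("smoothing must be 'exact' or 'all'")
    miss = len(ref - emb)  # p=1, q=eps
    log_term = np.log(1.0 / epsilon)
    n_pairs = n * (n - 1) // 2
    n_neg = n_pairs - len(ref)
    match_term = 0.0
    if smoothing == "all":
        n_matched = (n_pairs - len(ref | emb)) + len(ref & emb)
        match_term = n_matched * np.log(1.0 / (1.0 - epsilon))
    if negative_subsample == "all":
        spurious = len(emb - ref)  # p=0, q=1-eps
        kl = (miss + spurious) * log_term + match_term
        n_mismatch = miss + spurious
    else:
        m = int(negative_subsample)
        if m <= 0:
            raise ValueError("negative_subsample must be positive or 'all'")
        rng = np.random.default_rng(seed)
        spurious_hits = 0
        sampled: set[tuple[int, int]] = set()
        while len(sampled) < min(m, n_neg):
            i, j = int(rng.integers(n)), int(rng.integers(n))
            if i == j:
                continue
            e = (min(i, j), max(i, j))
            if e in ref or e in sampled:
                continue
            sampled.add(e)
            if e in emb:
                spurious_hits += 1
        scale = n_neg / max(len(sampled), 1)
        kl = miss * log_term + spurious_hits * scale * log_term + match_term
        n_mismatch = miss + spurious_hits
    return TopologyReport(
        kl=float(kl),
        n_ref_edges=len(ref),
        k_ref=k_ref,
        epsilon=epsilon,
        negative_subsample=negative_subsample,
        n_mismatched=n_mismatch,
    )


def distance_preservation_tau(X_highdim: np.ndarray, Z: Embedding | np.ndarray) -> float:
    """Kendall tau between the two condensed Euclidean distance matrices.

    Equals 1 for any embedding that is a rigid motion plus uniform scaling of
    the original coordinates, and ~0 for an unrelated embedding.
    """
    x = np.asarray(X_highdim, dtype=float)
    z = _as_array(Z)
    if x.shape[0] != z.shape[0]:
        raise ValueError("matrices must have the same number of cells")
    if x.shape[0] < 3:
        raise ValueError("need at least 3 cells")
    t = stats.kendalltau(pdist(x), pdist(z), variant="b").statistic
    return float(t)


def find_markers(
    m: NormMatrix,
    labels: LabelVector | np.ndarray,
    alpha: float = 0.05,
    top_n: int = 50,
    adjust: str | None = None,
) -> pd.DataFrame:
    """Per-cluster Wilcoxon rank-sum markers (cluster vs rest).

    Each gene is tested two-sided; small untied samples get the exact null
    distribution, larger ones the tie-corrected normal approximation.  Genes
    with p < ``alpha`` are ranked per cluster by the standardized rank-sum
    statistic (positive = up in the cluster) and truncated to ``top_n``.
    ``adjust="bh"`` applies Benjamini-Hochberg within each cluster first.
    Returns a table with columns cluster, gene, statistic, pvalue, rank.
    """
    lab = labels.labels if isinstance(labels, LabelVector) else np.asarray(labels)
    vals = m.values
    clusters = np.unique(lab)
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters to call markers")
    rows = []
    for c in clusters:
        in_c = lab == c
        n1, n2 = int(in_c.sum()), int((~in_c).sum())
        if n1 < 2:
            warnings.warn(f"cluster {c} has fewer than 2 cells; skipped", stacklevel=2)
            continue
        res = stats.mannwhitneyu(
            vals[in_c], vals[~in_c], alternative="two-sided", axis=0
        )
        u1 = np.asarray(res.statistic, dtype=float)
        pvals = np.asarray(res.pvalue, dtype=float)
        mu = n1 * n2 / 2.0
        # tie-corrected standard deviation of U for the ranking statistic
        sd = np.empty(vals.shape[1])
        nn = n1 + n2
        for gi in range(vals.shape[1]):
            _, counts = np.unique(vals[:, gi], return_counts=True)
            tie = np.sum(counts**3 - counts)
            sd[gi] = np.sqrt(
                n1 * n2 / 12.0 * ((nn + 1) - tie / (nn * (nn - 1)))
            )
        with np.errstate(divide="ignore", invalid="ignore"):
            zstat = np.where(sd > 0, (u1 - mu) / sd, 0.0)
        if adjust == "bh":
            pvals = _benjamini_hochberg(pvals)
        keep = np.where(pvals < alpha)[0]
        order = keep[np.argsort(-zstat[keep], kind="stable")][:top_n]
        for rank, gi in enumerate(order, start=1):
            rows.append(
                {
                    "cluster": int(c),
                    "gene": m.gene_ids[gi],
                    "statistic": float(zstat[gi]),
                    "pvalue": float(pvals[gi]),
                    "rank": rank,
                }
            )
    return pd.DataFrame(rows, columns=["cluster", "gene", "statistic", "pvalue", "rank"])


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        i = n - rank_from_end
        running = min(running, p[idx] * n / i)
        adj[idx] = running
    return adj


def silhouette_sweep(
    Z: Embedding | np.ndarray, k_range=range(2, 16), seed: int = 0, restarts: int = 10
) -> tuple[int, dict[int, float]]:
    """Pick K by maximizing average silhouette width over a K range."""
    scores = {}
    for k in k_range:
        lab = kmeans_cluster(Z, k, seed=seed, restarts=restarts)
        scores[k] = silhouette(Z, lab)
    best = max(scores, key=lambda k: (scores[k], -k))
    return best, scores
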