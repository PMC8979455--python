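"""Structure-aware gene sub-sampling with random-hyperplane LSH.

Genes (columns of the normalized matrix) are hashed by the sign pattern of
their dot products with ``n_bits`` random Gaussian hyperplanes — the classic
cosine-similarity LSH family — so co-expressed genes tend to collide in a
bucket.  Within each bucket a small cosine-distance kNN graph is built, and a
greedy sweep in dataset order keeps a gene while discarding its neighbours
(a discarded gene, when visited, is skipped but still discards its own
neighbours).  The survivors are a reduced, structure-preserving feature set;
the whole procedure can be applied recursively to shrink it further.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .preprocess import NormMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LSHConfig:
    n_bits: int = 10
    n_neighbors: int = 5
    iterations: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bits < 1 or self.n_neighbors < 1 or self.iterations < 1:
            raise ValueError("n_bits, n_neighbors and iterations must be >= 1")


@dataclass
class GeneSubset:
    """Selected gene indices (dataset order) plus the diagnostic bucket map."""

    selected: list[int]
    buckets: dict[int, list[int]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.selected)


def hash_genes(m: NormMatrix, cfg: LSHConfig) -> dict[int, list[int]]:
    """Assign every gene one n_bits-bit code from signed random projections.

    Requires more genes than buckets (|G| > 2^n_bits), mirroring the intended
    regime where buckets actually group several genes.
    """
    n_genes = m.n_genes
    if n_genes <= 2**cfg.n_bits:
        raise ValueError(
            f"{n_genes} genes <= 2^{cfg.n_bits} buckets; lower n_bits "
            f"(need n_bits < log2(n_genes))"
        )
    rng = np.random.default_rng(cfg.seed)
    planes = rng.standard_normal((m.n_cells, cfg.n_bits))
    bits = (m.values.T @ planes) >= 0  # (genes, n_bits)
    codes = bits @ (1 << np.arange(cfg.n_bits, dtype=np.int64))
    buckets: dict[int, list[int]] = {}
    for gene, code in enumerate(codes):
        buckets.setdefault(int(code), []).append(gene)
    return buckets


def bucket_knn(
    bucket: list[int], m: NormMatrix, n_neighbors: int = 5
) -> dict[int, list[int]]:
    """Cosine-distance nearest neighbours of each gene within one bucket.

    Buckets smaller than n_neighbors + 1 return all co-members.  Zero-vector
    genes are treated as maximally distant (cosine distance 1) from everything.
    Ties break by ascending gene index, keeping the result deterministic.
    """
    if not bucket:
        raise ValueError("bucket must be nonempty")
    idx = np.asarray(bucket)
    vecs = m.values[:, idx].T.astype(float)  # (b, cells)
    norms = np.linalg.norm(vecs, axis=1)
    zero = norms == 0
    if zero.any():
        logger.warning("%d zero-vector gene(s) in bucket; cosine distance set to 1", zero.sum())
    safe = np.where(zero, 1.0, norms)
    unit = vecs / safe[:, None]
    dist = 1.0 - unit @ unit.T
    dist[zero, :] = 1.0
    dist[:, zero] = 1.0
    np.fill_diagonal(dist, np.inf)
    out: dict[int, list[int]] = {}
    b = len(bucket)
    k = min(n_neighbors, b - 1)
    for row in range(b):
        if k == 0:
            out[int(idx[row])] = []
            continue
        order = np.lexsort((idx, dist[row]))[:k]  # distance, then gene index
        out[int(idx[row])] = [int(idx[j]) for j in order]
    return out


def greedy_select(
    knn: dict[int, list[int]], visit_order: list[int] | np.ndarray
) -> list[int]:
    """Sequential keep-or-discard sweep over genes in dataset order.

    A visited, not-yet-discarded gene is selected and its neighbours
    discarded; a visited gene that was already discarded is skipped but its
    neighbours are discarded too.  Total and deterministic.
    """
    discarded: set[int] = set()
    selected: list[int] = []
    for gene in visit_order:
        gene = int(gene)
        if gene not in discarded:
            selected.append(gene)
        discarded.update(knn.get(gene, ()))
    return selected


def sample_features(m: NormMatrix, cfg: LSHConfig) -> GeneSubset:
    """hash -> per-bucket kNN -> greedy sweep, repeated ``iterations`` times.

    Each iteration operates on the survivors of the previous one (hashing
    them afresh with a distinct seeded set of hyperplanes), so the selected
    set shrinks monotonically.  Selected indices refer to columns of ``m``
    and stay in dataset order.
    """
    current = np.arange(m.n_genes)
    last_buckets: dict[int, list[int]] = {}
    for it in range(cfg.iterations):
        sub = NormMatrix(
            m.values[:, current],
            m.cell_ids,
            [m.gene_ids[i] for i in current],
            provenance={"view": "lsh-iteration"},
        )
        it_cfg = LSHConfig(cfg.n_bits, cfg.n_neighbors, 1, cfg.seed + it)
        buckets_local = hash_genes(sub, it_cfg)
        knn_local: dict[int, list[int]] = {}
        for members in buckets_local.values():
            knn_local.update(bucket_knn(members, sub, cfg.n_neighbors))
        keep_local = greedy_select(knn_local, np.arange(len(current)))
        last_buckets = {
            code: [int(current[i]) for i in members]
            for code, members in buckets_local.items()
        }
        current = current[np.asarray(sorted(keep_local), dtype=int)]
        logger.info("LSH iteration %d: %d genes survive", it + 1, len(current))
    return GeneSubset(selected=[int(i) for i in current], buckets=last_buckets)


def sample_to_target(
    m: NormMatrix, cfg: LSHConfig, target_genes: int
) -> GeneSubset:
    """Repeat whole LSH rounds until <= target_genes or no further change,
    then truncate in visit (dataset) order."""
    current = np.arange(m.n_genes)
    round_seed = cfg.seed
    buckets: dict[int, list[int]] = {}
    while len(current) > target_genes:
        sub = NormMatrix(
            m.values[:, current], m.cell_ids,
            [m.gene_ids[i] for i in current], provenance={},
        )
        if len(current) <= 2**cfg.n_bits:
            break  # cannot hash further at this width
        res = sample_features(sub, LSHConfig(cfg.n_bits, cfg.n_neighbors, 1, round_seed))
        new = current[np.asarray(res.selected, dtype=int)]
        buckets = {c: [int(current[i]) for i in mem] for c, mem in res.buckets.items()}
        if len(new) == len(current):
            break
        current = new
        round_seed += 1
    return GeneSubset(selected=[int(i) for i in current[:target_genes]], buckets=buckets)
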