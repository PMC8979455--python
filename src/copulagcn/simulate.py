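"""Grouped scRNA-seq-like count simulation with planted structure.

A deliberately minimal splatter-style model: gene baseline means are Gamma
draws, each group perturbs a chosen fraction of genes by a lognormal fold
change with random sign, cells get lognormal library sizes, counts are
Poisson (optionally negative binomial) around the library-scaled group
means, and technical dropout zeroes entries with probability logistic in
the log mean — calibrated so the configured rate is the expected fraction
of *would-be-expressed* entries that get zeroed.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .metrics import LabelVector
from .preprocess import CountMatrix


@dataclass(frozen=True)
class SimSpec:
    n_cells: int = 500
    n_genes: int = 2000
    n_groups: int = 2
    group_probs: tuple[float, ...] | None = None  # None -> equal
    de_prop: float = 0.4
    de_logfc_scale: float = 1.0
    dropout_rate: float = 0.2
    mean_shape: float = 0.6
    mean_rate: float = 0.3
    libsize_logmean: float = 9.7
    libsize_logsd: float = 0.25
    dropout_shape: float = 1.0
    nb_dispersion: float | None = None  # None -> Poisson
    seed: int = 0

    def __post_init__(self) -> None:
        problems = []
        if self.n_groups < 1:
            problems.append("n_groups must be >= 1")
        if self.n_cells < self.n_groups:
            problems.append("n_cells must be >= n_groups")
        if not 0 <= self.de_prop <= 1:
            problems.append("de_prop must lie in [0, 1]")
        if not 0 <= self.dropout_rate < 1:
            problems.append("dropout_rate must lie in [0, 1)")
        if self.mean_shape <= 0 or self.mean_rate <= 0:
            problems.append("gamma hyperparameters must be > 0")
        if self.group_probs is not None:
            gp = np.asarray(self.group_probs, dtype=float)
            if len(gp) != self.n_groups:
                problems.append("group_probs length must equal n_groups")
            elif not np.isclose(gp.sum(), 1.0) or np.any(gp < 0):
                problems.append("group_probs must be nonnegative and sum to 1")
        if problems:
            raise ValueError("invalid SimSpec: " + "; ".join(problems))

    @property
    def probs(self) -> np.ndarray:
        if self.group_probs is None:
            return np.full(self.n_groups, 1.0 / self.n_groups)
        return np.asarray(self.group_probs, dtype=float)


@dataclass
class SimResult:
    counts: CountMatrix
    true_labels: LabelVector
    de_genes: list[np.ndarray] = field(repr=False)
    true_logfc: np.ndarray = field(repr=False)  # genes x groups, log2 scale


def _calibrate_dropout_midpoint(
    lam: np.ndarray, target: float, shape: float
) -> float:
    """Bisect the logistic midpoint so the expected dropout rate among
    would-be-nonzero entries equals ``target``."""
    log_lam = np.log(np.maximum(lam, 1e-12))
    w = 1.0 - np.exp(-lam)  # P(entry would be nonzero)
    w_sum = w.sum()

    def realized(x0: float) -> float:
        p = 1.0 / (1.0 + np.exp(-(x0 - log_lam) * shape))
        return float((p * w).sum() / w_sum)

    lo, hi = log_lam.min() - 20.0, log_lam.max() + 20.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if realized(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_counts(spec: SimSpec) -> SimResult:
    """Draw one grouped count matrix with ground truth attached."""
    rng = np.random.default_rng(spec.seed)
    g, n = spec.n_genes, spec.n_cells
    base_mean = rng.gamma(spec.mean_shape, 1.0 / spec.mean_rate, size=g)
    labels = rng.choice(spec.n_groups, size=n, p=spec.probs)
    # planted per-group DE: lognormal |log2 fold change|, random sign
    logfc = np.zeros((g, spec.n_groups))
    de_genes: list[np.ndarray] = []
    for k in range(spec.n_groups):
        n_de = int(round(spec.de_prop * g))
        chosen = rng.choice(g, size=n_de, replace=False)
        if n_de and spec.de_logfc_scale > 0:
            mag = rng.lognormal(
                mean=np.log(spec.de_logfc_scale), sigma=0.4, size=n_de
            )
            sign = rng.choice([-1.0, 1.0], size=n_de)
            logfc[chosen, k] = sign * mag
        de_genes.append(np.sort(chosen))
    group_mean = base_mean[:, None] * 2.0 ** logfc  # genes x groups
    group_prof = group_mean / group_mean.sum(axis=0, keepdims=True)
    libsize = rng.lognormal(spec.libsize_logmean, spec.libsize_logsd, size=n)
    lam = libsize[:, None] * group_prof[:, labels].T  # cells x genes
    if spec.nb_dispersion is None:
        counts = rng.poisson(lam)
    else:
        r = 1.0 / spec.nb_dispersion
        counts = rng.poisson(rng.gamma(r, lam / r))
    if spec.dropout_rate > 0:
        x0 = _calibrate_dropout_midpoint(lam, spec.dropout_rate, spec.dropout_shape)
        p_drop = 1.0 / (1.0 + np.exp(-(x0 - np.log(np.maximum(lam, 1e-12))) * spec.dropout_shape))
        counts = np.where(rng.uniform(size=counts.shape) < p_drop, 0, counts)
    cell_ids = [f"cell{i}" for i in range(n)]
    gene_ids = [f"gene{j}" for j in range(g)]
    return SimResult(
        counts=CountMatrix(counts.astype(np.int64), cell_ids, gene_ids),
        true_labels=LabelVector(labels=labels, cell_ids=cell_ids),
        de_genes=de_genes,
        true_logfc=logfc,
    )


# The four benchmark configurations: cells/classes growing together, all with
# 2000 genes, 20% dropout and 40% DE genes.
SERIES_CONFIGS = ((500, 2), (1000, 3), (1500, 4), (2000, 5))


def simulate_dataset_series(base_seed: int = 20) -> list[SimResult]:
    """The standard scaling series: 500/2, 1000/3, 1500/4, 2000/5 cells/groups."""
    out = []
    for i, (n_cells, n_groups) in enumerate(SERIES_CONFIGS):
        spec = SimSpec(
            n_cells=n_cells,
            n_groups=n_groups,
            n_genes=2000,
            de_prop=0.4,
            dropout_rate=0.2,
            seed=base_seed + i,
        )
        out.append(simulate_counts(spec))
    return out
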