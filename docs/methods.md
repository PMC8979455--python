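# Methods

This note records the model, the parameter choices and their rationale, what
the synthetic data does and does not emulate, and the numerical conventions
— the information a maintainer needs to trust or change the defaults.

## Preprocessing

Input is a cells × genes matrix of nonnegative integer counts (MTX with
barcode/gene sidecars, or delimited text). Two quality filters run in a
fixed order: first cells, keeping those with **strictly more than**
`min_genes_per_cell` (default 1000) genes at nonzero count; then genes,
keeping those whose count **exceeds** `min_count` (default 5) in **at
least** `min_cell_frac` (default 10%) of the *retained* cells. The
strict/inclusive readings and the cells-before-genes order are part of the
contract (filtering is idempotent and id order is preserved). Defaults suit
droplet data with ~20k genes; for the 2000-gene synthetic designs below the
cell filter is lowered to 100 detected genes, a scale-of-data adjustment,
not a different rule.

Normalization is per-cell library-size scaling to the median library
followed by log2(1 + x) (`method="size_factor"`), or log2(1 + x) alone
(`method="none"`) for matrices normalized upstream by heavier machinery
(e.g. variance-stabilizing transforms). The downstream dependence measure
is rank-based, so any monotone per-cell transform upstream leaves the cell
graph unchanged; the normalization mainly matters for the encoder features,
PCA baselines and marker statistics.

## LSH gene sampling

Gene profiles (columns) are hashed by the signs of dot products with
`n_bits` standard-normal hyperplanes — the cosine LSH family, one table.
`n_bits` defaults to 10 (≤1024 buckets) and requires more genes than
buckets; for smaller gene sets use fewer bits. Within each bucket every
gene's `n_neighbors = 5` cosine-nearest co-members are found (zero-profile
genes are treated as maximally distant; k-NN ties break by ascending gene
index for determinism). The greedy sweep visits genes in dataset order:
a not-yet-discarded gene is selected and its neighbours discarded; an
already-discarded gene is skipped but its neighbours are still discarded.
`iterations` (default 1) reruns the whole procedure on the survivors with a
fresh seeded hash, so selection shrinks monotonically; `sample_to_target`
repeats rounds until a target size is reached and truncates in dataset
order.

Properties worth knowing: duplicates of a gene collide and collapse to
roughly one representative per 6 copies at the default 5-NN; exactly
orthogonal genes that share a bucket are all-tied, so exactly one gene per
bucket survives — with load factor near 1 that is ~63% of genes, not "all".
The benefit of the sweep is coverage: redundant modules shed members while
every distinct pattern keeps one, which is visible as a higher Kendall
correlation between all-gene and selected-gene cell-distance matrices than
random subsets of equal size achieve (tested on planted-module data).

## Ccor and the cell graph

The dependence between two cells across the selected genes is Kendall's
tau. Through the copula representation τ = 4∬C dC − 1 the statistic
depends only on the copula of the joint distribution, hence is invariant to
monotone distortions of either profile — the property that motivates using
it on noisy counts. For the Clayton family, generator φ(x)=(x^−θ−1)/θ with
θ ∈ [−1,∞)\{0} (θ→0 giving independence), the relation has the closed form
τ = θ/(θ+2); `clayton_cdf`, `sample_clayton` (conditional inversion, valid
for negative θ) and `tau_from_theta`/`theta_from_tau` implement the family.

The default estimator for the cell-cell matrix is the empirical tau-b with
tie corrections. A fixed global Clayton θ cannot produce a data-dependent
pairwise score (τ(θ) is a constant), so the model parameter θ = −0.5 is
carried as a diagnostic: `mode="clayton"` maps each empirical tau through
θ(τ) and back, a round-trip parity check of the copula model. Two exact
integer-counting routes exist — Knight's O(n log n) merge-sort estimator
(`kendall_tau`) and an O(n²) pair-enumeration oracle (`kendall_tau_brute`)
— and the numba-compiled pairwise kernel used for the full matrix is pinned
bit-for-bit to them in the tests.

Each cell ranks all others by descending Ccor (ties by ascending index) and
the graph is the undirected union of directed top-k lists, k = 5 — a union
of 5-NN lists yields ~4.9 edges per node, matching the density regime the
method operates in. k is exposed (`--graph-k`).

## Graph autoencoder

Encoder: three propagation steps H^(l+1) = σ(D̂^−1/2 Â D̂^−1/2 H^(l) W^(l))
with Â = A + I, ReLU after layers 1–2, linear third layer; output dims
256/128/128 (the final 128-d Z is the cell embedding). The symmetric
normalization is used because it alone keeps the propagation operator's
spectrum in [−1, 1]. Node features default to the normalized expression
over the selected genes — the feature matrix produced by the LSH step.
Identity features (a free per-node embedding, folded in implicitly) remain
available; they are viable on well-mixed graphs but interact badly with the
fixed short training schedule below: when the cell graph splits into
near-disconnected communities, identity-feature embeddings of different
components overlap at random and k-means cannot find them, whereas
expression features separate groups from the first forward pass.

Decoder: σ(z_i·z_j) over all pairs. Training: 8:1:1 uniform edge split
(all nodes stay in the training graph; self-loops keep isolated nodes
propagating), negatives for validation/test sampled uniformly from
non-edges in matching number, binary cross-entropy over all n² pairs with
the positive class reweighted by (n² − 2|E|)/(2|E|), Adam (β = 0.9/0.999)
for 50 epochs at learning rate 0.001, dropout 0.1 after the two hidden
layers (inverted scaling). Weights are Glorot-uniform; the model is plain
NumPy with an explicit forward/backward pass, verified against numerical
gradients, fully deterministic given the seed, and trains in seconds on
dense CPU linear algebra at the graph sizes this package targets (≲10⁴
nodes; no minibatching or sparse path is provided beyond that). There is no
early stopping — the epoch budget is part of the protocol.

Untrained encoders are *not* chance-level link predictors on structured
graphs: propagation alone correlates neighbouring rows. Chance behaviour
appears only on structure-free (Erdős–Rényi) graphs, which is how the
untrained baseline is tested.

## Clustering and evaluation

k-means (k-means++ with 10 restarts, best inertia, seeded) clusters Z; K is
user-supplied where ground truth defines it, otherwise a silhouette-
maximizing sweep over K ∈ [2, 15] is available. ARI and average silhouette
width come from scikit-learn (singleton clusters score 0 and are warned
about).

**Topology preservation.** The reference P is the 0/1 indicator of the
kNN graph (k_ref = 5, same union-of-directed-lists construction as the cell
graph) built on the high-dimensional matrix; Q is the ε-smoothed indicator
(ε = 1e−4) of the kNN graph built on the embedding with the same k. The
reported KL(P,Q) uses the exact-agreement convention: q_e = p_e wherever
the two indicators agree, so agreeing pairs contribute zero, each
disagreeing pair contributes log(1/ε), and KL = 0 exactly iff the graphs
coincide; KL is then mismatch-count × log(1/ε), monotone in graph overlap.
A fully-smoothed variant (every pair contributes, floor of
log(1/(1−ε)) per agreeing pair) is available via `smoothing="all"`. Above
~2000 cells the quadratic non-edge set can be uniformly subsampled with the
negative term rescaled — an unbiased estimator whose variance the tests
check.

**Distance preservation.** Kendall tau between the condensed Euclidean
distance matrices of the high-dimensional data (all post-filter genes by
default; a flag restricts to the selected genes) and the embedding. Exactly
1 under rigid motion + uniform scaling. Note the ceiling: an embedding
derived from a binary 5-NN graph cannot retain global distance ranks, so
its tau (~0.2–0.3 on the simulated designs) sits well below that of linear
projections of the full matrix (~0.7 for a random 128-d projection); the
score is most informative when comparing graph-derived embeddings with one
another.

**Markers.** Per cluster, each gene gets a two-sided Wilcoxon rank-sum test
(cluster vs rest): exact null distribution for small untied samples,
tie-corrected normal approximation otherwise (scipy's `mannwhitneyu`,
`method="auto"`). Genes with p < α = 0.05 are ranked by the standardized
statistic (positive = up in cluster) and truncated to the top 50. Raw
p-values are the default to match the usual single-marker workflow;
Benjamini–Hochberg is available (`adjust="bh"`). Null calibration (~5% kept
at α = 0.05, uniform null p-values) is tested by simulation.

## Synthetic data

The simulator is a deliberately minimal splatter-style model. Baseline gene
means are Gamma(shape 0.6, rate 0.3); each group assigns a `de_prop`
fraction of genes (default 0.4) a lognormal |log2 fold change| (median
`de_logfc_scale`, default 1.0, i.e. typical 2-fold; σ = 0.4 on the log)
with random sign; cells draw lognormal library sizes (log-mean 9.7 ≈ 16k
reads, log-sd 0.25); counts are Poisson around library-scaled group
profiles, optionally Gamma-mixed into a negative binomial
(`nb_dispersion`); dropout zeroes entries with probability logistic in
−log(mean) (shape 1), with the midpoint bisected on the drawn rate matrix
so that the expected dropout rate *among would-be-nonzero entries* equals
`dropout_rate` (default 0.2) — so the realized zero fraction is
approximately sampling-zeros + dropout_rate × (1 − sampling-zeros). The
four-dataset scaling series fixes (cells, groups) = (500,2), (1000,3),
(1500,4), (2000,5) at 2000 genes each with distinct fixed seeds.

What the simulator does *not* emulate: batch effects, continuous
trajectories, gene-gene co-expression modules beyond the group structure,
cell-cycle covariates, and empirically-fitted per-dataset parameters.
Passing tests on this data therefore demonstrates the machinery recovers
*planted discrete group structure under dropout noise*; it does not certify
performance on real tissue atlases.

The benchmark design used throughout (`benchmarks.DATA1`) is 500 cells in
two equiprobable groups with the defaults above. On it the full method
attains ARI 1.0 per seed (matching a PCA-128 + k-means reference) with
held-out-edge ROC ≈ 0.84–0.97; these are recomputed, not stored, by
`scripts/acceptance.py` and the acceptance tests.

## Numerical conventions and degenerate inputs

- Constant vectors: pseudo-observations 0.5, Kendall tau 0, both with
  warnings; constant cell profiles give zero Ccor rows (warned).
- Clayton CDF uses the generator pseudo-inverse clamp max(·,0)^(−1/θ) and
  exact boundary values C(u,0)=0, C(u,1)=u; θ = 0 returns uv.
- Neighbor-rank and k-NN ties always break by ascending index; all
  stochastic steps (hyperplanes, splits, negative sampling, dropout masks,
  k-means) draw from seeded generators, and the pipeline fans one global
  seed out as seed + stage-index.
- Edge splits refuse graphs with fewer than 10 edges; hashing refuses
  |genes| ≤ 2^n_bits; filters that empty the matrix raise rather than
  return empty objects.
- Non-finite training loss aborts with the epoch and learning rate.

## Known limitations

- The pairwise-tau matrix is O(n² · g log g); ~500 cells × ~800 genes takes
  ~10 s (numba). Beyond ~5k cells, subsample cells or genes first.
- Dense adjacency in the autoencoder caps practical graph size at ~10⁴
  nodes on one CPU.
- The SBM link-prediction testbed has an information ceiling (~0.76 ROC for
  its standard parameters) set by the block structure itself; real kNN cell
  graphs are much more predictable (~0.84–0.97 observed), and the
  planted-partition number should be read against that ceiling, not
  against real-graph figures.
- θ is a global diagnostic parameter; no per-pair copula fitting is done.
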