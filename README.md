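# copulagcn

Clustering single-cell RNA-seq data by combining a copula-based cell-cell
dependence measure with a graph-convolutional autoencoder.

Cell-type discovery from scRNA-seq counts is usually a pipeline: normalize,
select genes, reduce dimension, cluster. Two standard weak points are the
gene-selection step (variance-based selection is unstable in high dimension
and ignores redundancy) and the similarity measure used to relate cells
(Pearson/Euclidean are sensitive to the scale and the heavy technical noise
of counts). This package addresses both:

1. **Structure-aware gene sampling (LSH).** Genes are hashed by the sign
   pattern of random Gaussian projections of their expression profiles
   (cosine locality-sensitive hashing), so co-expressed genes collide in
   buckets. Within each bucket a 5-NN cosine graph is built, and a greedy
   sweep in dataset order keeps a gene while discarding its neighbours.
   Redundant genes are pruned while distinct expression patterns keep a
   representative; the procedure can be applied recursively.

2. **Copula correlation (Ccor) cell graph.** The dependence between two
   cells over the sampled genes is Kendall's tau, which by Sklar's theorem
   depends on the joint distribution only through its copula — it is
   invariant under any monotone distortion of either cell's profile. The
   Clayton family with generator φ(x) = (x^−θ − 1)/θ links the model
   parameter to the dependence scale via τ = θ/(θ+2); empirically τ is
   estimated by the tie-corrected tau-b statistic (exact O(n log n)
   merge-sort counting). Each cell ranks all others by Ccor and the cell
   graph is the undirected union of the top-k (k = 5) choices.

3. **Graph autoencoder embedding.** A 3-layer GCN encoder (output dims
   256/128/128) propagates the normalized-expression node features through
   D̂^−1/2 (A+I) D̂^−1/2 and an inner-product decoder σ(z_i·z_j)
   reconstructs edges. Training minimizes class-reweighted cross-entropy on
   an 8:1:1 train/validation/test edge split (50 epochs, Adam, lr 0.001,
   dropout 0.1); held-out edges give ROC/AP link-prediction scores. The
   128-d embedding Z is clustered with k-means.

Evaluation utilities cover ARI and average silhouette width, a
topology-preservation score (KL divergence between the kNN-graph indicator
of the high-dimensional data and the ε-smoothed kNN indicator of the
embedding), the Kendall correlation between high- and low-dimensional
distance matrices, and per-cluster Wilcoxon rank-sum marker detection. A
splatter-style simulator generates grouped count matrices with planted
ground truth so the whole method is testable offline.

## Worked example

```bash
python examples/simulate_and_cluster.py
```

simulates 200 cells in two groups (600 genes, 20% dropout, 40% DE genes),
runs the full pipeline and prints the report:

```json
{
  "n_cells": 200,
  "n_genes_filtered": 468,
  "n_genes_selected": 300,
  "graph_edges": 944,
  "k_clusters": 2,
  "asw": 0.76,
  "topology_kl": 13898.4,
  "distance_tau": 0.23,
  "linkpred": {"val_roc": 0.90, "val_ap": 0.91, "test_roc": 0.91, "test_ap": 0.91},
  "ari": 1.0
}
```

ARI = 1.0: k-means on the embedding recovered the two planted groups
exactly. The autoencoder ranked held-out cell-graph edges above sampled
non-edges with ROC ≈ 0.91, and the embedding kept a positive share of the
cell-cell distance ordering (τ ≈ 0.23 over all pairs). Other entry points:

```bash
python examples/copula_basics.py        # Clayton generator/CDF, tau-theta relation
python examples/lsh_gene_sampling.py    # redundancy pruning on duplicated genes
python examples/link_prediction.py      # GAE on a planted two-clique graph
python examples/topology_and_markers.py # embedding metrics + marker detection
copulagcn run --input counts.tsv --k-clusters 8 --seed 1 --outdir run/   # CLI
```

The CLI also exposes each stage (`simulate`, `preprocess`, `sample`,
`graph`, `embed`, `cluster`, `evaluate`) operating on a shared run
directory, with every parameter available as a flag or YAML config.

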