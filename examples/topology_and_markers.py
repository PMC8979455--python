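"""Embedding-quality metrics and marker detection on controlled inputs.

Shows that the topology-KL score is 0 for a distance-preserving embedding
and grows as the embedding is corrupted, that the distance tau is exactly 1
under a rigid transform, and that a gene expressed in one group only is
found as its top marker.
"""
import numpy as np

from copulagcn import (
    NormMatrix,
    distance_preservation_tau,
    find_markers,
    topology_kl,
)

rng = np.random.default_rng(3)
X = np.vstack([rng.normal(0, 1, (40, 10)), rng.normal(4, 1, (40, 10))])

q, _ = np.linalg.qr(rng.normal(size=(10, 10)))
rigid = 2.0 * X @ q + 5.0
print("rigid transform:     KL =", topology_kl(X, rigid).kl,
      " distance tau =", distance_preservation_tau(X, rigid))

noisy = X + rng.normal(0, 2.0, X.shape)
shuffled = X[rng.permutation(len(X))]
print(f"noisy embedding:     KL = {topology_kl(X, noisy).kl:8.1f}  "
      f"distance tau = {distance_preservation_tau(X, noisy):.3f}")
print(f"shuffled embedding:  KL = {topology_kl(X, shuffled).kl:8.1f}  "
      f"distance tau = {distance_preservation_tau(X, shuffled):.3f}")

vals = rng.uniform(0, 1, size=(80, 30))
vals[:40, 12] += 4.0  # gene12 high only in group 0
nm = NormMatrix(vals, [f"c{i}" for i in range(80)], [f"g{j}" for j in range(30)], {})
labels = np.array([0] * 40 + [1] * 40)
top = find_markers(nm, labels).query("cluster == 0").head(3)
print("\ntop markers for group 0 (gene, z-statistic, p):")
for _, row in top.iterrows():
    print(f"  {row.gene:>4}  z={row.statistic:6.2f}  p={row.pvalue:.2e}")
print("gene g12 leads because it is expressed only in group 0; the KL/tau "
      "columns above quantify how corruption degrades neighbourhood structure.")
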