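"""Graph-convolutional autoencoder over the cell graph.

A three-layer GCN encoder propagates features through the symmetrically
normalized adjacency with self-loops, D^-1/2 (A + I) D^-1/2, and an
inner-product decoder sigmoid(z_i . z_j) reconstructs edge probabilities.
Node features default to the identity, so the first-layer weight acts as a
free per-node embedding.  Training minimizes a class-reweighted binary
cross-entropy between decoded probabilities and the training adjacency with
Adam; held-out edges (plus sampled non-edges) give ROC / average-precision
link-prediction scores.

The whole model is plain NumPy: at the scale of cell graphs handled here
(10^2-10^4 nodes) dense CPU linear algebra trains in seconds, and an
explicit forward/backward keeps every arithmetic step inspectable and
bit-reproducible under a seed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .graph import CellGraph


class TrainingDiverged(RuntimeError):
    pass


@dataclass
class EdgeSplit:
    train_edges: list[tuple[int, int]]
    val_edges: list[tuple[int, int]]
    test_edges: list[tuple[int, int]]
    val_neg: list[tuple[int, int]]
    test_neg: list[tuple[int, int]]
    seed: int


@dataclass(frozen=True)
class GCNParams:
    layer_dims: tuple[int, int, int] = (256, 128, 128)
    dropout: float = 0.1
    learning_rate: float = 0.001
    epochs: int = 50
    activation: str = "relu"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.layer_dims) != 3:
            raise ValueError("encoder is a 3-layer GCN: layer_dims must have length 3")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")
        if self.activation != "relu":
            raise ValueError("only ReLU activation is supported")

    @property
    def embedding_dim(self) -> int:
        return self.layer_dims[-1]


@dataclass
class Embedding:
    Z: np.ndarray
    cell_ids: list[str]

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.Z)):
            raise ValueError("embedding contains non-finite entries")
        if self.Z.shape[0] != len(self.cell_ids):
            raise ValueError("embedding rows must match cell ids")


@dataclass
class LinkPredReport:
    val_roc: float
    val_ap: float
    test_roc: float
    test_ap: float

    def __post_init__(self) -> None:
        for v in (self.val_roc, self.val_ap, self.test_roc, self.test_ap):
            if not 0 <= v <= 1:
                raise ValueError("link-prediction scores must lie in [0, 1]")


def split_edges(
    g: CellGraph,
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> EdgeSplit:
    """Randomly partition undirected edges 8:1:1 and sample matching non-edges.

    All nodes stay in the training graph (self-loops guarantee degree >= 1);
    only edges are held out.  Negatives are drawn uniformly without
    replacement from unordered non-adjacent pairs, as many as there are
    validation / test positives.
    """
    if not math.isclose(sum(ratios), 1.0):
        raise ValueError("ratios must sum to 1")
    edges = sorted(g.edges)
    n_edges = len(edges)
    if n_edges < 10:
        raise ValueError(f"graph has only {n_edges} edges; split would be degenerate")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_edges)
    n_val = int(round(ratios[1] * n_edges))
    n_test = int(round(ratios[2] * n_edges))
    val_idx = perm[:n_val]
    test_idx = perm[n_val : n_val + n_test]
    train_idx = perm[n_val + n_test :]
    edge_set = set(edges)
    n = g.n_nodes
    n_pairs = n * (n - 1) // 2
    if n_pairs - n_edges < n_val + n_test:
        raise ValueError("not enough non-edges to sample negatives")
    negatives: list[tuple[int, int]] = []
    seen: set[tuple[int, int]] = set()
    while len(negatives) < n_val + n_test:
        i = int(rng.integers(n))
        j = int(rng.integers(n))
        if i == j:
            continue
        e = (min(i, j), max(i, j))
        if e in edge_set or e in seen:
            continue
        seen.add(e)
        negatives.append(e)
    return EdgeSplit(
        train_edges=[edges[i] for i in train_idx],
        val_edges=[edges[i] for i in val_idx],
        test_edges=[edges[i] for i in test_idx],
        val_neg=negatives[:n_val],
        test_neg=negatives[n_val : n_val + n_test],
        seed=seed,
    )


def _adjacency_from_edges(n: int, edges) -> np.ndarray:
    a = np.zeros((n, n))
    for i, j in edges:
        a[i, j] = a[j, i] = 1.0
    return a


def normalize_adjacency(g: CellGraph | np.ndarray) -> np.ndarray:
    """Symmetric normalization with self-loops: D^-1/2 (A + I) D^-1/2.

    Spectral radius <= 1, so repeated propagation cannot blow up; an isolated
    node keeps its self-loop (degree 1) and maps to the identity row.
    """
    a = g.adjacency() if isinstance(g, CellGraph) else np.asarray(g, dtype=float)
    a_hat = a + np.eye(a.shape[0])
    d = a_hat.sum(axis=1)
    d_inv_sqrt = 1.0 / np.sqrt(d)
    return a_hat * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def init_weights(n_nodes: int, params: GCNParams, rng: np.random.Generator) -> list[np.ndarray]:
    d0, d1, d2 = params.layer_dims
    return [_glorot(rng, n_nodes, d0), _glorot(rng, d0, d1), _glorot(rng, d1, d2)]


def gcn_encode(
    A_norm: np.ndarray,
    params: GCNParams,
    weights: list[np.ndarray],
    X: np.ndarray | None = None,
    *,
    training: bool = False,
    rng: np.random.Generator | None = None,
    cell_ids: list[str] | None = None,
    _cache: dict | None = None,
) -> Embedding:
    """Three propagation steps; ReLU after layers 1-2, linear output Z.

    ``X=None`` means identity node features, folded in implicitly (the first
    weight is indexed rather than multiplied).  Dropout acts only when
    ``training`` is set, using inverted scaling so evaluation needs no rescale.
    """
    n = A_norm.shape[0]
    if X is not None and X.shape[0] != n:
        raise ValueError("feature matrix rows must match number of nodes")
    if weights[0].shape[0] != (n if X is None else X.shape[1]):
        raise ValueError(
            f"first weight expects input dim {weights[0].shape[0]}, "
            f"got {n if X is None else X.shape[1]}"
        )
    keep = 1.0 - params.dropout
    XW = weights[0] if X is None else X @ weights[0]
    pre1 = A_norm @ XW
    h1 = np.maximum(pre1, 0.0)
    if training and params.dropout > 0:
        mask1 = (rng.uniform(size=h1.shape) < keep) / keep
        h1d = h1 * mask1
    else:
        mask1 = None
        h1d = h1
    pre2 = A_norm @ (h1d @ weights[1])
    h2 = np.maximum(pre2, 0.0)
    if training and params.dropout > 0:
        mask2 = (rng.uniform(size=h2.shape) < keep) / keep
        h2d = h2 * mask2
    else:
        mask2 = None
        h2d = h2
    z = A_norm @ (h2d @ weights[2])
    if _cache is not None:
        _cache.update(
            XW=XW, pre1=pre1, h1d=h1d, mask1=mask1,
            pre2=pre2, h2d=h2d, mask2=mask2, X=X,
        )
    ids = cell_ids if cell_ids is not None else [f"cell{i}" for i in range(n)]
    return Embedding(Z=z, cell_ids=ids)


def inner_product_decode(Z: Embedding | np.ndarray, i: int, j: int) -> float:
    """Edge probability sigmoid(z_i . z_j); symmetric in its arguments."""
    z = Z.Z if isinstance(Z, Embedding) else np.asarray(Z)
    return float(_sigmoid(z[i] @ z[j]))


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def _softplus(x):
    return np.logaddexp(0.0, x)


def _edge_scores(z: np.ndarray, edges) -> np.ndarray:
    idx = np.asarray(edges)
    return _sigmoid(np.einsum("ij,ij->i", z[idx[:, 0]], z[idx[:, 1]]))


def train_gae(
    g: CellGraph,
    params: GCNParams,
    split: EdgeSplit,
    cell_ids: list[str] | None = None,
    X: np.ndarray | None = None,
) -> tuple[Embedding, LinkPredReport, list[np.ndarray]]:
    """Train the autoencoder on the training-edge adjacency with Adam.

    Loss is binary cross-entropy between decoded probabilities and the
    training adjacency over all node pairs, with the positive class
    reweighted by (n^2 - 2|E|) / (2|E|) to offset sparsity.  Propagation uses
    the training edges only, so held-out edges are genuinely unseen.  Returns
    the evaluation-mode embedding, the validation/test link-prediction
    report, and the trained weights; every random draw comes from the seed in
    ``params``.
    """
    n = g.n_nodes
    rng = np.random.default_rng(params.seed)
    a_train = _adjacency_from_edges(n, split.train_edges)
    a_norm = normalize_adjacency(a_train)
    n_pos = 2 * len(split.train_edges)
    if n_pos == 0:
        raise ValueError("no training edges")
    pos_weight = (n * n - n_pos) / n_pos
    weights = init_weights(n if X is None else X.shape[1], params, rng)
    mom = [np.zeros_like(w) for w in weights]
    vel = [np.zeros_like(w) for w in weights]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    lr = params.learning_rate
    loss_history: list[float] = []
    for epoch in range(params.epochs):
        cache: dict = {}
        emb = gcn_encode(
            a_norm, params, weights, X, training=True, rng=rng, _cache=cache
        )
        z = emb.Z
        s = z @ z.T
        # weighted BCE on logits, averaged over all n^2 ordered pairs
        loss = float(
            np.mean(pos_weight * a_train * _softplus(-s) + (1 - a_train) * _softplus(s))
        )
        if not np.isfinite(loss):
            raise TrainingDiverged(
                f"non-finite loss at epoch {epoch} (lr={lr}); "
                "inspect the graph or lower the learning rate"
            )
        loss_history.append(loss)
        p = _sigmoid(s)
        g_s = ((1.0 + (pos_weight - 1.0) * a_train) * p - pos_weight * a_train) / (n * n)
        dz = (g_s + g_s.T) @ z
        # backprop through Z = A (H2d W2)
        t2 = a_norm @ dz
        grad2 = cache["h2d"].T @ t2
        dh2 = t2 @ weights[2].T
        if cache["mask2"] is not None:
            dh2 = dh2 * cache["mask2"]
        dh2 = dh2 * (cache["pre2"] > 0)
        t1 = a_norm @ dh2
        grad1 = cache["h1d"].T @ t1
        dh1 = t1 @ weights[1].T
        if cache["mask1"] is not None:
            dh1 = dh1 * cache["mask1"]
        dh1 = dh1 * (cache["pre1"] > 0)
        dxw = a_norm @ dh1
        grad0 = dxw if X is None else X.T @ dxw
        for w, m_, v_, grad in zip(weights, mom, vel, [grad0, grad1, grad2]):
            m_ *= beta1
            m_ += (1 - beta1) * grad
            v_ *= beta2
            v_ += (1 - beta2) * grad**2
            t = epoch + 1
            m_hat = m_ / (1 - beta1**t)
            v_hat = v_ / (1 - beta2**t)
            w -= lr * m_hat / (np.sqrt(v_hat) + eps)
    emb = gcn_encode(a_norm, params, weights, X, training=False, cell_ids=cell_ids)
    report = evaluate_link_prediction(emb.Z, split)
    report.loss_history = loss_history  # type: ignore[attr-defined]
    return emb, report, weights


def evaluate_link_prediction(z: np.ndarray, split: EdgeSplit) -> LinkPredReport:
    """ROC-AUC and average precision on held-out positives vs sampled negatives."""
    def _scores(pos, neg):
        y = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
        s = np.concatenate([_edge_scores(z, pos), _edge_scores(z, neg)])
        return y, s

    yv, sv = _scores(split.val_edges, split.val_neg)
    yt, st = _scores(split.test_edges, split.test_neg)
    return LinkPredReport(
        val_roc=float(roc_auc_score(yv, sv)),
        val_ap=float(average_precision_score(yv, sv)),
        test_roc=float(roc_auc_score(yt, st)),
        test_ap=float(average_precision_score(yt, st)),
    )
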