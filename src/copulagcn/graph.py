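"""Cell-cell dependence matrix (Ccor) and the kNN cell graph.

Every cell pair gets a Kendall tau-b score computed across the sampled genes;
because tau is rank-based it inherits the scale-invariance of the underlying
copula (any strictly monotone distortion of a cell's profile leaves its
scores unchanged).  Each cell ranks all others by descending score and the
graph is the undirected union of the top-k choices.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._fast_tau import pairwise_tau
from .copula import ClaytonParams, tau_from_theta, theta_from_tau
from .lsh import GeneSubset
from .preprocess import NormMatrix


@dataclass
class CcorMatrix:
    """Symmetric cells x cells dependence matrix with unit diagonal."""

    values: np.ndarray
    cell_ids: list[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("Ccor matrix must be square")
        if not np.allclose(v, v.T):
            raise ValueError("Ccor matrix must be symmetric")
        if np.any(v < -1 - 1e-12) or np.any(v > 1 + 1e-12):
            raise ValueError("Ccor entries must lie in [-1, 1]")
        self.values = v

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]


@dataclass
class CellGraph:
    """Undirected cell graph: edge set plus each node's full ranked list."""

    n_nodes: int
    edges: set[tuple[int, int]]
    ranked_lists: list[list[int]] = field(repr=False)

    def __post_init__(self) -> None:
        for i, j in self.edges:
            if i == j:
                raise ValueError("self-loops are not allowed")
            if not (0 <= i < self.n_nodes and 0 <= j < self.n_nodes):
                raise ValueError("edge endpoint out of range")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self) -> np.ndarray:
        a = np.zeros((self.n_nodes, self.n_nodes))
        for i, j in self.edges:
            a[i, j] = a[j, i] = 1.0
        return a

    def neighbors(self, node: int) -> set[int]:
        return {j for i, j in self.edges if i == node} | {
            i for i, j in self.edges if j == node
        }


def ccor_matrix(
    m: NormMatrix,
    genes: GeneSubset | list[int] | None = None,
    mode: str = "empirical_tau",
    theta: float = -0.5,
) -> CcorMatrix:
    """Pairwise Kendall tau-b between cells over the sampled genes.

    ``mode="empirical_tau"`` (default) scores each pair by the tie-corrected
    empirical estimator.  ``mode="clayton"`` is a diagnostic parity mode: each
    empirical tau is mapped to the Clayton parameter via tau = theta/(theta+2)
    and back, verifying the copula-model round trip (values are unchanged up
    to float error); the fixed global ``theta`` is the model parameter
    reported in its provenance.
    """
    sel = None
    if isinstance(genes, GeneSubset):
        sel = genes.selected
    elif genes is not None:
        sel = list(genes)
    vals = m.values if sel is None else m.values[:, sel]
    n, g = vals.shape
    if n < 2 or g < 2:
        raise ValueError("need >= 2 cells and >= 2 selected genes")
    if mode not in ("empirical_tau", "clayton"):
        raise ValueError(f"unknown mode {mode!r}")
    constant = np.all(vals == vals[:, :1], axis=1)
    if constant.any():
        warnings.warn(f"{constant.sum()} constant cell profile(s): tau set to 0", stacklevel=2)
    out = pairwise_tau(vals)
    if mode == "clayton":
        mask = ~np.eye(n, dtype=bool) & (np.abs(out) < 1)
        out[mask] = np.array(
            [tau_from_theta(theta_from_tau(t)) for t in out[mask]]
        )
    _ = ClaytonParams(theta)  # validate the model parameter
    return CcorMatrix(out, list(m.cell_ids))


def build_knn_graph(c: CcorMatrix, k: int = 5) -> CellGraph:
    """Union of every cell's directed top-k by descending Ccor.

    Ties break by ascending node index.  Each node's full ranked neighbour
    list (all other nodes) is retained for inspection.
    """
    n = c.n_cells
    if k >= n:
        raise ValueError(f"k={k} must be < number of cells ({n})")
    vals = c.values
    edges: set[tuple[int, int]] = set()
    ranked: list[list[int]] = []
    idx = np.arange(n)
    for i in range(n):
        others = idx[idx != i]
        # descending Ccor, ties by ascending index (lexsort keys in reverse order)
        order = others[np.lexsort((others, -vals[i, others]))]
        ranked.append([int(j) for j in order])
        for j in order[:k]:
            edges.add((min(i, int(j)), max(i, int(j))))
    return CellGraph(n_nodes=n, edges=edges, ranked_lists=ranked)


def write_edge_list(g: CellGraph, cell_ids: list[str], path, c: CcorMatrix | None = None) -> None:
    """Two id columns per row, optional third column with the Ccor weight."""
    with open(path, "w") as fh:
        for i, j in sorted(g.edges):
            if c is not None:
                fh.write(f"{cell_ids[i]}\t{cell_ids[j]}\t{c.values[i, j]:.6f}\n")
            else:
                fh.write(f"{cell_ids[i]}\t{cell_ids[j]}\n")
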