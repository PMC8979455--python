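"""Shared fixtures: small synthetic inputs and graph builders."""
from __future__ import annotations

import numpy as np
import pytest

import copulagcn as cg
from copulagcn.graph import CellGraph


@pytest.fixture(scope="session")
def small_sim() -> cg.SimResult:
    """200 cells / 600 genes / 2 groups — fast but structured."""
    return cg.simulate_counts(
        cg.SimSpec(n_cells=200, n_genes=600, n_groups=2, seed=11)
    )


@pytest.fixture(scope="session")
def small_norm(small_sim) -> cg.NormMatrix:
    return cg.preprocess(small_sim.counts, min_genes_per_cell=50)


def make_planted_graph(
    n: int = 200, p_in: float = 0.3, p_out: float = 0.02, seed: int = 0
) -> CellGraph:
    """Two-block planted-partition random graph."""
    rng = np.random.default_rng(seed)
    half = n // 2
    edges = set()
    for i in range(n):
        for j in range(i + 1, n):
            p = p_in if (i < half) == (j < half) else p_out
            if rng.uniform() < p:
                edges.add((i, j))
    return CellGraph(n_nodes=n, edges=edges, ranked_lists=[])


def make_two_cliques(half: int = 30) -> CellGraph:
    """Two disjoint complete blocks — perfectly separable link structure."""
    edges = set()
    for off in (0, half):
        for i in range(half):
            for j in range(i + 1, half):
                edges.add((off + i, off + j))
    return CellGraph(n_nodes=2 * half, edges=edges, ranked_lists=[])


def make_er_graph(n: int = 120, p: float = 0.08, seed: int = 0) -> CellGraph:
    rng = np.random.default_rng(seed)
    edges = {
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if rng.uniform() < p
    }
    return CellGraph(n_nodes=n, edges=edges, ranked_lists=[])
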