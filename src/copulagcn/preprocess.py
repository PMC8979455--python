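"""Count-matrix IO, quality filters and normalization.

The pipeline starts from a cells x genes matrix of unique-molecule counts.
Cells with too few detected genes are discarded, then genes that are not
robustly expressed across the retained cells; the surviving counts are put on
a log2 scale, optionally after per-cell library-size scaling.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse


class PreprocessError(ValueError):
    """Raised for malformed inputs or filters that empty the matrix."""


def _check_ids(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})[:5]
        raise PreprocessError(f"duplicate {what} ids: {dupes}")
    return ids


@dataclass
class CountMatrix:
    """Integer expression counts, cells in rows, genes in columns."""

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise PreprocessError("counts must be a 2-D matrix")
        if np.any(self.values < 0):
            raise PreprocessError("counts must be nonnegative")
        self.cell_ids = _check_ids(self.cell_ids, "cell")
        self.gene_ids = _check_ids(self.gene_ids, "gene")
        n, g = self.values.shape
        if n != len(self.cell_ids) or g != len(self.gene_ids):
            raise PreprocessError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.cell_ids)} cells / {len(self.gene_ids)} genes"
            )

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


@dataclass
class NormMatrix:
    """log2-scale expression (entries >= 0), with a record of how it was made."""

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise PreprocessError("shape inconsistent with ids")
        if np.any(self.values < 0):
            raise PreprocessError("normalized entries must be >= 0 (log2 of 1+count)")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


def read_counts(
    path: str | Path,
    format: str = "delimited",
    *,
    transpose: bool = False,
    sep: str | None = None,
) -> CountMatrix:
    """Read a count matrix from MTX (with sidecar name files) or delimited text.

    Parameters
    ----------
    path
        For ``format="mtx"``, the ``.mtx`` file; ``<stem>.barcodes.txt`` and
        ``<stem>.genes.txt`` sidecars (one id per line) must sit next to it.
        For ``format="delimited"``, a table whose header row holds gene ids and
        whose first column holds cell ids.
    transpose
        Set when the source is stored genes x cells.
    """
    path = Path(path)
    if not path.exists():
        raise PreprocessError(f"no such file: {path}")
    if format == "mtx":
        try:
            mat = spio.mmread(path)
        except Exception as exc:  # scipy reports the offending line
            raise PreprocessError(f"malformed MTX {path}: {exc}") from exc
        values = np.asarray(sparse.coo_matrix(mat).todense())
        rows = _read_id_file(path.with_suffix("").with_suffix(".barcodes.txt"))
        cols = _read_id_file(path.with_suffix("").with_suffix(".genes.txt"))
        if transpose:
            values = values.T
            rows, cols = cols, rows
        return CountMatrix(values.astype(np.int64), rows, cols)
    if format == "delimited":
        try:
            header = pd.read_csv(path, sep=sep, engine="python", header=None, nrows=1)
            raw_cols = [str(v) for v in header.iloc[0, 1:]]
            df = pd.read_csv(path, sep=sep, index_col=0, engine="python")
        except Exception as exc:
            raise PreprocessError(f"malformed table {path}: {exc}") from exc
        if len(set(raw_cols)) != len(raw_cols):
            kind = "cell" if transpose else "gene"
            raise PreprocessError(f"duplicate {kind} ids in header of {path}")
        if transpose:
            df = df.T
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise PreprocessError(f"non-numeric entries in {path}")
        return CountMatrix(
            np.asarray(np.rint(values), dtype=np.int64),
            list(df.index.astype(str)),
            list(df.columns.astype(str)),
        )
    raise PreprocessError(f"unknown format {format!r} (use 'mtx' or 'delimited')")


def _read_id_file(path: Path) -> list[str]:
    if not path.exists():
        raise PreprocessError(f"missing MTX sidecar id file: {path}")
    return [line.strip() for line in path.read_text().splitlines() if line.strip()]


def write_counts(m: CountMatrix, path: str | Path, format: str = "delimited") -> None:
    """Inverse of :func:`read_counts` (same sidecar conventions for MTX)."""
    path = Path(path)
    if format == "mtx":
        spio.mmwrite(path, sparse.coo_matrix(m.values))
        path.with_suffix("").with_suffix(".barcodes.txt").write_text(
            "\n".join(m.cell_ids) + "\n"
        )
        path.with_suffix("").with_suffix(".genes.txt").write_text(
            "\n".join(m.gene_ids) + "\n"
        )
    elif format == "delimited":
        pd.DataFrame(m.values, index=m.cell_ids, columns=m.gene_ids).to_csv(
            path, sep="\t"
        )
    else:
        raise PreprocessError(f"unknown format {format!r}")


def filter_cells_genes(
    m: CountMatrix,
    min_genes_per_cell: int = 1000,
    min_count: int = 5,
    min_cell_frac: float = 0.10,
) -> CountMatrix:
    """Apply the two quality filters, cells first.

    Keeps cells with strictly more than ``min_genes_per_cell`` genes showing a
    nonzero count, then keeps genes whose count exceeds ``min_count`` (strict)
    in at least ``min_cell_frac`` (inclusive) of the retained cells.
    """
    if min_genes_per_cell < 0 or min_count < 0 or min_cell_frac < 0:
        raise PreprocessError("filter thresholds must be >= 0")
    cell_keep = (m.values > 0).sum(axis=1) > min_genes_per_cell
    if not cell_keep.any():
        raise PreprocessError("empty after filtering: no cell passed the gene-detection filter")
    vals = m.values[cell_keep]
    n_kept = vals.shape[0]
    gene_keep = (vals > min_count).sum(axis=0) >= min_cell_frac * n_kept
    if not gene_keep.any():
        raise PreprocessError("empty after filtering: no gene passed the expression filter")
    return CountMatrix(
        vals[:, gene_keep],
        [c for c, k in zip(m.cell_ids, cell_keep) if k],
        [g for g, k in zip(m.gene_ids, gene_keep) if k],
    )


def normalize_log(m: CountMatrix, method: str = "size_factor") -> NormMatrix:
    """Library-size scaling (to the median library) followed by log2(1 + x).

    ``method="none"`` skips the scaling step, for matrices normalized upstream.
    """
    if m.values.size == 0:
        raise PreprocessError("cannot normalize an empty matrix")
    vals = m.values.astype(float)
    if method == "size_factor":
        lib = vals.sum(axis=1)
        if np.any(lib == 0):
            raise PreprocessError("cell with zero total count; filter cells first")
        vals = vals * (np.median(lib) / lib)[:, None]
    elif method != "none":
        raise PreprocessError(f"unknown normalization method {method!r}")
    out = np.log2(vals + 1.0)
    return NormMatrix(
        out,
        list(m.cell_ids),
        list(m.gene_ids),
        provenance={"method": method, "log": "log2(1+x)"},
    )


def preprocess(
    m: CountMatrix,
    min_genes_per_cell: int = 1000,
    min_count: int = 5,
    min_cell_frac: float = 0.10,
    norm: str = "size_factor",
) -> NormMatrix:
    """Filter then normalize; the standard entry point for raw counts."""
    filtered = filter_cells_genes(m, min_genes_per_cell, min_count, min_cell_frac)
    if filtered.n_genes < 3:
        warnings.warn("fewer than 3 genes survived filtering", stacklevel=2)
    out = normalize_log(filtered, method=norm)
    out.provenance.update(
        filters={
            "min_genes_per_cell": min_genes_per_cell,
            "min_count": min_count,
            "min_cell_frac": min_cell_frac,
        },
        n_cells_in=m.n_cells,
        n_genes_in=m.n_genes,
    )
    return out
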