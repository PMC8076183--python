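"""Incidence / contingency tables and their file formats.

The central object is :class:`IncidenceTable`: a nonnegative matrix ``A``
(``n_r`` rows by ``n_c`` columns) holding joint counts of two categorical
variables — equivalently the bi-adjacency matrix of a bipartite network in
which row nodes (e.g. species) connect to column nodes (e.g. sites).  Row
margins ``r``, column margins ``c`` and the grand total ``n`` double as node
degrees and edge count of that network.

Tables are read from dense CSV/TSV (labels in the header row and first
column) or from MatrixMarket coordinate files with optional one-label-per-line
sidecar files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = ["IncidenceTable", "load_incidence"]

# Below this density tables are kept in CSR storage and eigenproblems are
# solved with truncated sparse SVD.
SPARSE_DENSITY_THRESHOLD = 0.05


@dataclass(frozen=True)
class IncidenceTable:
    """A validated nonnegative contingency table with margins.

    Attributes
    ----------
    values
        Dense ndarray or CSR matrix of nonnegative counts (or 0/1 presences).
    row_labels, col_labels
        Unique identifiers for the row and column categories.
    dropped_rows, dropped_cols
        Labels removed at load time because their margin was zero.
    """

    values: np.ndarray | sp.csr_matrix
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    dropped_rows: tuple[str, ...] = field(default=())
    dropped_cols: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        vals = self.values
        if sp.issparse(vals):
            vals = sp.csr_matrix(vals)
        else:
            vals = np.asarray(vals, dtype=float)
            if vals.ndim != 2:
                raise ValueError("incidence table must be a 2-d matrix")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "row_labels", tuple(str(l) for l in self.row_labels))
        object.__setattr__(self, "col_labels", tuple(str(l) for l in self.col_labels))
        n_r, n_c = vals.shape
        if len(self.row_labels) != n_r or len(self.col_labels) != n_c:
            raise ValueError("label count does not match matrix shape")
        if len(set(self.row_labels)) != n_r or len(set(self.col_labels)) != n_c:
            raise ValueError("row and column labels must be unique")
        self._check_nonnegative()
        if self.total <= 0:
            raise ValueError("incidence table is all zero")
        if np.any(self.row_margins == 0):
            bad = self.row_labels[int(np.argmin(self.row_margins))]
            raise ValueError(
                f"row {bad!r} has zero margin; load with drop_empty=True to prune"
            )
        if np.any(self.col_margins == 0):
            bad = self.col_labels[int(np.argmin(self.col_margins))]
            raise ValueError(
                f"column {bad!r} has zero margin; load with drop_empty=True to prune"
            )

    def _check_nonnegative(self) -> None:
        vals = self.values
        data = vals.data if sp.issparse(vals) else vals
        if data.size and np.min(data) < 0:
            if sp.issparse(vals):
                coo = vals.tocoo()
                k = int(np.argmin(coo.data))
                i, j = int(coo.row[k]), int(coo.col[k])
            else:
                i, j = np.unravel_index(int(np.argmin(vals)), vals.shape)
            raise ValueError(
                f"negative entry at row {self.row_labels[i]!r}, "
                f"column {self.col_labels[j]!r}"
            )

    # -- margins ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def row_margins(self) -> np.ndarray:
        """Row degrees r_i = sum_j A_ij."""
        return np.asarray(self.values.sum(axis=1)).ravel()

    @property
    def col_margins(self) -> np.ndarray:
        """Column degrees c_j = sum_i A_ij."""
        return np.asarray(self.values.sum(axis=0)).ravel()

    @property
    def total(self) -> float:
        """Grand total n = sum_ij A_ij (edge count for a binary table)."""
        return float(self.values.sum())

    @property
    def density(self) -> float:
        nnz = self.values.nnz if sp.issparse(self.values) else np.count_nonzero(self.values)
        return nnz / (self.n_rows * self.n_cols)

    @property
    def is_sparse(self) -> bool:
        return sp.issparse(self.values)

    def dense(self) -> np.ndarray:
        """The table as a dense float ndarray."""
        return self.values.toarray() if sp.issparse(self.values) else np.array(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dense(), index=list(self.row_labels), columns=list(self.col_labels))

    def subset_rows(self, labels: Sequence[str]) -> "IncidenceTable":
        """Restrict to the given rows, pruning columns that become empty.

        Used when a cluster of rows is re-analysed on its own: the child must
        again be a valid table with strictly positive margins.
        """
        wanted = set(map(str, labels))
        idx = [i for i, l in enumerate(self.row_labels) if l in wanted]
        if not idx:
            raise ValueError("row subset is empty")
        sub = self.values[idx, :]
        col_sums = np.asarray(sub.sum(axis=0)).ravel()
        keep = np.flatnonzero(col_sums > 0)
        dropped = tuple(self.col_labels[j] for j in np.flatnonzero(col_sums == 0))
        return IncidenceTable(
            values=sub[:, keep],
            row_labels=[self.row_labels[i] for i in idx],
            col_labels=[self.col_labels[j] for j in keep],
            dropped_cols=dropped,
        )

    # -- serialisation ---------------------------------------------------
    def to_csv(self, path: str | Path, sep: str = ",") -> None:
        self.to_frame().to_csv(path, sep=sep)

    def to_mtx(self, path: str | Path) -> None:
        path = Path(path)
        scipy.io.mmwrite(path, sp.coo_matrix(self.values))
        path.with_suffix(".rows.txt").write_text("\n".join(self.row_labels) + "\n")
        path.with_suffix(".cols.txt").write_text("\n".join(self.col_labels) + "\n")


def _from_arrays(
    values: np.ndarray | sp.spmatrix,
    row_labels: Sequence[str],
    col_labels: Sequence[str],
    drop_empty: bool,
) -> IncidenceTable:
    sparse = sp.issparse(values)
    if sparse:
        values = sp.csr_matrix(values)
        data = values.data
    else:
        values = np.asarray(values, dtype=float)
        data = values
    row_labels = [str(l) for l in row_labels]
    col_labels = [str(l) for l in col_labels]
    if data.size and np.min(data) < 0:
        # delegate the error message to the validator so the cell is named
        return IncidenceTable(values, row_labels, col_labels)

    dropped_rows: tuple[str, ...] = ()
    dropped_cols: tuple[str, ...] = ()
    if drop_empty:
        r = np.asarray(values.sum(axis=1)).ravel()
        c = np.asarray(values.sum(axis=0)).ravel()
        keep_r = np.flatnonzero(r > 0)
        keep_c = np.flatnonzero(c > 0)
        dropped_rows = tuple(row_labels[i] for i in np.flatnonzero(r == 0))
        dropped_cols = tuple(col_labels[j] for j in np.flatnonzero(c == 0))
        values = values[keep_r, :][:, keep_c]
        row_labels = [row_labels[i] for i in keep_r]
        col_labels = [col_labels[j] for j in keep_c]
    if not sparse and values.size:
        nnz = np.count_nonzero(values)
        if nnz / values.size < SPARSE_DENSITY_THRESHOLD and min(values.shape) > 50:
            values = sp.csr_matrix(values)
    return IncidenceTable(values, row_labels, col_labels, dropped_rows, dropped_cols)


def load_incidence(
    source,
    *,
    fmt: str | None = None,
    drop_empty: bool = True,
    row_label_file: str | Path | None = None,
    col_label_file: str | Path | None = None,
    sep: str | None = None,
) -> IncidenceTable:
    """Load an incidence table from a file, DataFrame or array.

    Parameters
    ----------
    source
        Path to a CSV/TSV (labels in header and first column) or MatrixMarket
        ``.mtx`` file, or an in-memory DataFrame / array / sparse matrix.
    fmt
        ``"csv"`` or ``"mtx"``; inferred from the file extension when omitted.
    drop_empty
        Remove all-zero rows/columns instead of rejecting them; removals are
        recorded on the returned table.
    row_label_file, col_label_file
        Label sidecars for MatrixMarket input (one label per line).  Default:
        ``<stem>.rows.txt`` / ``<stem>.cols.txt`` next to the matrix if they
        exist, otherwise positional ``R0001...`` / ``C0001...`` names.
    """
    if isinstance(source, pd.DataFrame):
        return _from_arrays(source.to_numpy(dtype=float), source.index, source.columns, drop_empty)
    if isinstance(source, IncidenceTable):
        return source
    if isinstance(source, (np.ndarray, list)) or sp.issparse(source):
        mat = source if sp.issparse(source) else np.asarray(source, dtype=float)
        n_r, n_c = mat.shape
        rows = [f"R{i + 1:04d}" for i in range(n_r)]
        cols = [f"C{j + 1:04d}" for j in range(n_c)]
        return _from_arrays(mat, rows, cols, drop_empty)

    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    if fmt is None:
        fmt = "mtx" if path.suffix.lower() == ".mtx" else "csv"
    if fmt == "mtx":
        mat = sp.csr_matrix(scipy.io.mmread(path))
        rows = _read_labels(row_label_file or path.with_suffix(".rows.txt"), mat.shape[0], "R")
        cols = _read_labels(col_label_file or path.with_suffix(".cols.txt"), mat.shape[1], "C")
        return _from_arrays(mat, rows, cols, drop_empty)
    if fmt == "csv":
        if sep is None:
            sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
        frame = pd.read_csv(path, sep=sep, index_col=0)
        return _from_arrays(frame.to_numpy(dtype=float), frame.index, frame.columns, drop_empty)
    raise ValueError(f"unknown format {fmt!r}; expected 'csv' or 'mtx'")


def _read_labels(path: str | Path, expected: int, prefix: str) -> list[str]:
    path = Path(path)
    if not path.exists():
        return [f"{prefix}{i + 1:04d}" for i in range(expected)]
    labels = [line.strip() for line in path.read_text().splitlines() if line.strip()]
    if len(labels) != expected:
        raise ValueError(
            f"label file {path} has {len(labels)} entries, expected {expected}"
        )
    return labels
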