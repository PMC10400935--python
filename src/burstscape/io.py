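"""Readers and writers for expression matrices and tabular outputs.

Two input formats are supported for cells x genes matrices:

* a delimited table whose first row holds gene identifiers and whose first
  column holds cell identifiers;
* a MatrixMarket coordinate file (cells x genes) accompanied by one-id-per-line
  gene and cell files.

Both round-trip bit-exactly for integer matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


@dataclass
class ExpressionMatrix:
    """Cells x genes expression values with identifiers.

    Attributes
    ----------
    values : ndarray, shape (n_cells, n_genes)
        Non-negative expression values; integer counts after normalisation.
    cell_ids, gene_ids : list of str
        Unique row / column identifiers.
    capture_time : ndarray or None
        Optional per-cell experimental capture time (used to root lineages).
    """

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    capture_time: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D cells x genes array")
        if np.any(self.values < 0):
            raise ValueError("expression values must be non-negative")
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if len(self.cell_ids) != self.values.shape[0]:
            raise ValueError("cell_ids length does not match values")
        if len(self.gene_ids) != self.values.shape[1]:
            raise ValueError("gene_ids length does not match values")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("cell_ids must be unique")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids must be unique")
        if self.capture_time is not None:
            self.capture_time = np.asarray(self.capture_time, dtype=float)
            if self.capture_time.shape != (self.values.shape[0],):
                raise ValueError("capture_time length does not match cells")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset_cells(self, mask: np.ndarray) -> "ExpressionMatrix":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return replace(
            self,
            values=self.values[idx],
            cell_ids=[self.cell_ids[i] for i in idx],
            capture_time=None if self.capture_time is None
            else self.capture_time[idx],
        )

    def subset_genes(self, mask: np.ndarray) -> "ExpressionMatrix":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return replace(
            self,
            values=self.values[:, idx],
            gene_ids=[self.gene_ids[i] for i in idx],
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.cell_ids,
                          columns=self.gene_ids)
        df.index.name = "cell_id"
        return df


def read_expression_table(path: str | Path, sep: str = ",") -> ExpressionMatrix:
    """Read a delimited cells x genes table (gene ids in the header row)."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    return ExpressionMatrix(
        values=df.to_numpy(),
        cell_ids=[str(i) for i in df.index],
        gene_ids=[str(c) for c in df.columns],
    )


def write_expression_table(
    matrix: ExpressionMatrix, path: str | Path, sep: str = ","
) -> None:
    """Write the matrix as a delimited table mirroring the reader layout."""
    matrix.to_dataframe().to_csv(path, sep=sep)


def read_expression_mtx(
    mtx_path: str | Path, cells_path: str | Path, genes_path: str | Path
) -> ExpressionMatrix:
    """Read a MatrixMarket coordinate matrix plus one-id-per-line files."""
    m = scipy.io.mmread(mtx_path)
    if scipy.sparse.issparse(m):
        m = m.toarray()
    cell_ids = Path(cells_path).read_text().split()
    gene_ids = Path(genes_path).read_text().split()
    return ExpressionMatrix(values=np.asarray(m), cell_ids=cell_ids,
                            gene_ids=gene_ids)


def write_expression_mtx(
    matrix: ExpressionMatrix,
    mtx_path: str | Path,
    cells_path: str | Path,
    genes_path: str | Path,
) -> None:
    values = matrix.values
    sp = scipy.sparse.coo_matrix(values)
    field_kind = "integer" if np.issubdtype(values.dtype, np.integer) else None
    scipy.io.mmwrite(str(mtx_path), sp, field=field_kind)
    Path(cells_path).write_text("\n".join(matrix.cell_ids) + "\n")
    Path(genes_path).write_text("\n".join(matrix.gene_ids) + "\n")


def read_capture_times(path: str | Path) -> pd.Series:
    """Read a (cell_id, time) CSV into a Series indexed by cell id."""
    df = pd.read_csv(path)
    return pd.Series(df.iloc[:, 1].to_numpy(dtype=float),
                     index=df.iloc[:, 0].astype(str), name="capture_time")


def write_capture_times(matrix: ExpressionMatrix, path: str | Path) -> None:
    if matrix.capture_time is None:
        raise ValueError("matrix has no capture times")
    pd.DataFrame(
        {"cell_id": matrix.cell_ids, "capture_time": matrix.capture_time}
    ).to_csv(path, index=False)
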