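"""Pre-processing of single-cell expression matrices.

The model-based stages consume integer counts bounded by the fitting grid's
``m_max``, so pre-processing (i) caps the matrix by a single global rescaling,
(ii) removes poorly covered cells and rarely detected genes, and (iii) keeps
the most variable genes.  All filters are idempotent.
"""

from __future__ import annotations

import numpy as np

from .io import ExpressionMatrix

__all__ = [
    "normalize_counts",
    "filter_cells",
    "filter_genes",
    "select_variable_genes",
]


def normalize_counts(matrix: ExpressionMatrix, m_max: int) -> ExpressionMatrix:
    """Cap expression at ``m_max`` by one global rescaling, then round.

    If the matrix-wide maximum exceeds ``m_max`` every entry is multiplied by
    ``m_max / max``; entries are then rounded half-up to integers.  A single
    global factor (rather than per-gene scaling) preserves relative expression
    between genes; the telegraph fit absorbs a common scale through theta_t.
    Zeros stay zero.
    """
    values = np.asarray(matrix.values, dtype=float)
    if np.any(values < 0):
        raise ValueError("expression values must be non-negative")
    global_max = values.max() if values.size else 0.0
    if global_max > m_max:
        values = values * (m_max / global_max)
    # round half-up for platform determinism (np.round rounds half-to-even)
    values = np.floor(values + 0.5).astype(np.int64)
    out = ExpressionMatrix(
        values=values,
        cell_ids=list(matrix.cell_ids),
        gene_ids=list(matrix.gene_ids),
        capture_time=matrix.capture_time,
    )
    return out


def filter_cells(
    matrix: ExpressionMatrix, min_fraction_expressed: float
) -> ExpressionMatrix:
    """Keep cells expressing (value > 0) at least the given fraction of genes.

    Mirrors per-dataset rules such as removing cells in which fewer than
    70-75% of the assayed genes are detected.
    """
    if not 0.0 <= min_fraction_expressed <= 1.0:
        raise ValueError("min_fraction_expressed must be in [0, 1]")
    frac = (matrix.values > 0).mean(axis=1)
    return matrix.subset_cells(frac >= min_fraction_expressed)


def filter_genes(
    matrix: ExpressionMatrix, min_cell_fraction_nonzero: float
) -> ExpressionMatrix:
    """Keep genes detected (value > 0) in at least the given fraction of cells."""
    if not 0.0 <= min_cell_fraction_nonzero <= 1.0:
        raise ValueError("min_cell_fraction_nonzero must be in [0, 1]")
    frac = (matrix.values > 0).mean(axis=0)
    return matrix.subset_genes(frac >= min_cell_fraction_nonzero)


def select_variable_genes(
    matrix: ExpressionMatrix, n_genes: int
) -> ExpressionMatrix:
    """Keep the ``n_genes`` genes with the largest variance across cells.

    Variance is computed on the (normalised integer) values themselves; the
    downstream model consumes counts, so no log transform is applied.  Ties
    are broken by gene-id order so the selection is deterministic.
    """
    if not 1 <= n_genes <= matrix.n_genes:
        raise ValueError(
            f"n_genes must be in 1..{matrix.n_genes}, got {n_genes}")
    var = np.var(np.asarray(matrix.values, dtype=float), axis=0)
    order = sorted(range(matrix.n_genes),
                   key=lambda g: (-var[g], matrix.gene_ids[g]))
    keep = sorted(order[:n_genes])  # preserve original column order
    return matrix.subset_genes(np.asarray(keep))
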