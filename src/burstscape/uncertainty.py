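"""Transcriptional-uncertainty summaries and the landscape surface.

A cell's uncertainty is its placement NLL; the per-gene NLL matrix recorded
at each cell's optimal placement supports cluster-level averages, moving
windows along differentiation paths, selection of high-uncertainty genes, and
the landscape: NLL plotted as a surface over a 2-D embedding of the z-scored
expression data, fitted on a regular 30x30 grid by penalised least squares.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.sparse
import scipy.sparse.linalg
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

__all__ = [
    "mean_gene_cluster_nll",
    "moving_average_nll",
    "high_uncertainty_genes",
    "embed_2d",
    "GridSurface",
    "landscape_surface",
]


def mean_gene_cluster_nll(
    gene_cell_nll: np.ndarray, labels: np.ndarray
) -> pd.DataFrame:
    """Average gene-wise NLL per cluster: NLLbar_{g,k} = sum_{n in k} NLL_{g,n} / N_k.

    Returns a genes x clusters DataFrame (columns are the sorted cluster
    labels).
    """
    M = np.asarray(gene_cell_nll, dtype=float)
    labels = np.asarray(labels)
    if M.shape[0] != labels.size:
        raise ValueError("labels must cover all cells")
    ks = sorted(int(k) for k in np.unique(labels))
    out = {}
    for k in ks:
        members = labels == k
        if not members.any():
            raise ValueError(f"cluster {k} is empty")
        out[k] = M[members].mean(axis=0)
    return pd.DataFrame(out)


def moving_average_nll(
    pseudotime: np.ndarray,
    nll: np.ndarray,
    window_fraction: float = 0.10,
    cell_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Moving-window average of NLL over pseudotime-ordered cells.

    The window length is ``ceil(window_fraction * n)`` cells (10% of the
    path's cells by default); windows advance one cell at a time and each
    contributes its mean pseudotime and mean NLL.  Pseudotime ties are broken
    by cell id for determinism.
    """
    pseudotime = np.asarray(pseudotime, dtype=float)
    nll = np.asarray(nll, dtype=float)
    n = pseudotime.size
    if n < 1:
        raise ValueError("at least one cell is required")
    if cell_ids is None:
        cell_ids = [str(i) for i in range(n)]
    order = sorted(range(n), key=lambda i: (pseudotime[i], cell_ids[i]))
    t = pseudotime[order]
    y = nll[order]
    w = int(np.ceil(window_fraction * n))
    w = max(1, min(w, n))
    rows = [
        {"pseudotime": t[i:i + w].mean(), "nll": y[i:i + w].mean()}
        for i in range(n - w + 1)
    ]
    return pd.DataFrame(rows)


def high_uncertainty_genes(
    gene_cell_nll: np.ndarray,
    labels: np.ndarray,
    gene_ids: list[str] | None = None,
    frac_cells: float = 0.30,
    n_sd: float = 3.0,
) -> dict[int, list[str]]:
    """Genes whose NLL exceeds delta in enough cells of a cluster.

    The threshold delta is ``mean + n_sd * SD`` over all entries of the
    per-gene per-cell NLL matrix.  Gene g belongs to cluster k's set when
    strictly more-than-delta NLL values occur in at least ``frac_cells`` of
    the cluster's cells.
    """
    M = np.asarray(gene_cell_nll, dtype=float)
    if M.size == 0:
        raise ValueError("empty NLL matrix")
    labels = np.asarray(labels)
    if gene_ids is None:
        gene_ids = [f"gene_{g}" for g in range(M.shape[1])]
    delta = M.mean() + n_sd * M.std()
    out: dict[int, list[str]] = {}
    for k in sorted(int(k) for k in np.unique(labels)):
        members = M[labels == k]
        n_k = members.shape[0]
        n_exceed = (members > delta).sum(axis=0)
        keep = n_exceed >= frac_cells * n_k
        out[k] = [gene_ids[g] for g in np.flatnonzero(keep)]
    return out


def embed_2d(
    values: np.ndarray,
    method: str = "pca",
    random_state: int = 0,
) -> np.ndarray:
    """2-D embedding of z-scored expression for the landscape x-y plane.

    Genes are z-scored (constant genes are dropped with a warning) and
    projected with PCA (first two components, sign fixed so the
    largest-magnitude loading of each component is positive) or seeded t-SNE.
    """
    X = np.asarray(values, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("at least two genes are required")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        warnings.warn(
            f"dropping {int((sd == 0).sum())} constant gene(s) before "
            "z-scoring", stacklevel=2)
        X = X[:, sd > 0]
        sd = sd[sd > 0]
        if X.shape[1] < 2:
            raise ValueError("fewer than two non-constant genes")
    Z = (X - X.mean(axis=0)) / sd
    if method == "pca":
        pca = PCA(n_components=2, svd_solver="full")
        coords = pca.fit_transform(Z)
        for j in range(2):
            load = pca.components_[j]
            if load[np.argmax(np.abs(load))] < 0:
                coords[:, j] = -coords[:, j]
        return coords
    if method == "tsne":
        tsne = TSNE(n_components=2, random_state=random_state, init="pca")
        return tsne.fit_transform(Z)
    raise ValueError(f"unknown embedding method {method!r}")


class GridSurface(RegressorMixin, BaseEstimator):
    """Penalised least-squares surface on a regular grid (gridfit-style).

    ``fit(coords, z)`` places a ``grid_n`` x ``grid_n`` regular grid over the
    bounding box of the 2-D coordinates and solves for node heights that
    trade off (a) bilinear interpolation error at the data points against
    (b) a second-difference (Laplacian) roughness penalty weighted by
    ``smoothness``.  Constants and planes lie in the penalty's null space and
    are reproduced exactly.  A singular system triggers an automatic increase
    of the smoothness with a warning.

    Attributes
    ----------
    node_x_, node_y_ : ndarray (grid_n,)
        Grid node coordinates.
    node_z_ : ndarray (grid_n, grid_n)
        Fitted surface heights, indexed [iy, ix].
    """

    def __init__(self, grid_n: int = 30, smoothness: float = 1.0) -> None:
        self.grid_n = grid_n
        self.smoothness = smoothness

    def _interp_matrix(self, coords: np.ndarray) -> scipy.sparse.csr_matrix:
        n = self.grid_n
        x = np.clip(coords[:, 0], self.node_x_[0], self.node_x_[-1])
        y = np.clip(coords[:, 1], self.node_y_[0], self.node_y_[-1])
        ix = np.clip(np.searchsorted(self.node_x_, x, side="right") - 1,
                     0, n - 2)
        iy = np.clip(np.searchsorted(self.node_y_, y, side="right") - 1,
                     0, n - 2)
        dx = self.node_x_[1] - self.node_x_[0]
        dy = self.node_y_[1] - self.node_y_[0]
        tx = (x - self.node_x_[ix]) / dx
        ty = (y - self.node_y_[iy]) / dy
        rows = np.repeat(np.arange(coords.shape[0]), 4)
        cols = np.concatenate([
            iy * n + ix, iy * n + ix + 1,
            (iy + 1) * n + ix, (iy + 1) * n + ix + 1,
        ]).reshape(4, -1).T.ravel()
        vals = np.stack([
            (1 - tx) * (1 - ty), tx * (1 - ty),
            (1 - tx) * ty, tx * ty,
        ], axis=1).ravel()
        return scipy.sparse.csr_matrix(
            (vals, (rows, cols)), shape=(coords.shape[0], n * n))

    def fit(self, coords: np.ndarray, z: np.ndarray):
        coords = np.asarray(coords, dtype=float)
        z = np.asarray(z, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise ValueError("coords must be (n, 2)")
        if coords.shape[0] < 3:
            raise ValueError("at least 3 points are required")
        if np.linalg.matrix_rank(
                np.column_stack([coords, np.ones(len(coords))])) < 3:
            raise ValueError("points are collinear; no surface is defined")
        n = self.grid_n
        self.node_x_ = np.linspace(coords[:, 0].min(), coords[:, 0].max(), n)
        self.node_y_ = np.linspace(coords[:, 1].min(), coords[:, 1].max(), n)
        A = self._interp_matrix(coords)
        # second differences along each grid direction
        e = np.ones(n)
        d2 = scipy.sparse.diags([e[:-1], -2 * e, e[:-1]], [-1, 0, 1],
                                shape=(n, n)).tocsr()[1:-1]
        eye = scipy.sparse.identity(n, format="csr")
        Dx = scipy.sparse.kron(eye, d2)   # along x within each row
        Dy = scipy.sparse.kron(d2, eye)   # along y within each column
        P = (Dx.T @ Dx + Dy.T @ Dy).tocsc()
        AtA = (A.T @ A).tocsc()
        Atz = A.T @ z
        # scale the penalty so smoothness ~1 balances data and roughness
        scale = coords.shape[0] / (n * n)
        lam = self.smoothness * scale
        for attempt in range(6):
            system = AtA + lam * P
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sol = scipy.sparse.linalg.spsolve(system, Atz)
            if np.all(np.isfinite(sol)):
                break
            lam *= 100.0
            warnings.warn(
                "singular landscape system; increasing smoothness",
                stacklevel=2)
        self.node_z_ = sol.reshape(n, n)
        self.smoothness_used_ = lam / scale
        return self

    def predict(self, coords: np.ndarray) -> np.ndarray:
        """Bilinear interpolation of the fitted surface at new points."""
        coords = np.asarray(coords, dtype=float)
        return self._interp_matrix(coords) @ self.node_z_.ravel()

    def grid_frame(self) -> pd.DataFrame:
        """Long-format (x, y, z) table of the grid nodes."""
        xx, yy = np.meshgrid(self.node_x_, self.node_y_)
        return pd.DataFrame(
            {"x": xx.ravel(), "y": yy.ravel(), "z": self.node_z_.ravel()})


def landscape_surface(
    coords2d: np.ndarray,
    nll: np.ndarray,
    grid_n: int = 30,
    smoothness: float = 1.0,
) -> GridSurface:
    """Fit the uncertainty landscape: NLL over a 2-D embedding on a regular grid."""
    return GridSurface(grid_n=grid_n, smoothness=smoothness).fit(coords2d, nll)
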