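"""Burst-statistics correlations and RNA-velocity comparisons.

Pairwise Pearson correlations between per-(gene, cluster) burst size /
frequency and the cluster-averaged gene NLL quantify how transcriptional
uncertainty tracks bursting; significance uses the Pearson t score
``t = r * sqrt((n-2)/(1-r^2))`` with n-2 degrees of freedom.  Cell-wise RNA
velocity (Euclidean norm of the per-gene velocity vector) is compared with
cell-wise mean NLL along pseudotime via a lagged cross-correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "CorrelationRecord",
    "pearson_with_t",
    "burst_uncertainty_table",
    "cellwise_velocity_and_nll",
    "lagged_cross_correlation",
    "VelocitySummary",
]


@dataclass
class CorrelationRecord:
    """Pearson correlation with its t score and two-sided p-value."""

    name: str
    r: float
    n: int
    t: float
    p: float
    significant: bool


@dataclass
class VelocitySummary:
    """Per-cell velocity magnitude and mean NLL over a gene panel."""

    velocity_norm: np.ndarray
    mean_nll: np.ndarray

    def to_frame(self, cell_ids=None, pseudotime=None) -> pd.DataFrame:
        d = {"velocity_norm": self.velocity_norm, "mean_nll": self.mean_nll}
        if pseudotime is not None:
            d["pseudotime"] = np.asarray(pseudotime)
        df = pd.DataFrame(d)
        if cell_ids is not None:
            df.insert(0, "cell_id", list(cell_ids))
        return df


def pearson_with_t(
    x: np.ndarray, y: np.ndarray, name: str = "",
    p_threshold: float = 0.01,
) -> CorrelationRecord:
    """Pearson r with t score t = r*sqrt((n-2)/(1-r^2)) and two-sided p.

    Perfect correlation yields an infinite t and p reported as 0.  Constant
    input has no defined correlation and raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError("at least 3 observations are required")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation is undefined for a constant vector")
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        t = np.inf if r > 0 else -np.inf
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * scipy.stats.t.sf(abs(t), df=n - 2))
    return CorrelationRecord(name=name, r=r, n=n, t=float(t), p=p,
                             significant=p <= p_threshold)


def burst_uncertainty_table(
    cluster_params: pd.DataFrame,
    mean_nll: pd.DataFrame,
    p_threshold: float = 0.01,
    gene_ids: list[str] | None = None,
) -> tuple[CorrelationRecord, CorrelationRecord]:
    """Correlate burst frequency and burst size with cluster-mean gene NLL.

    ``cluster_params`` is the long table from
    :meth:`ClusteringResult.params_frame` (gene, cluster, burst_size,
    burst_frequency); ``mean_nll`` is the genes x clusters frame from
    :func:`mean_gene_cluster_nll`, whose rows follow the gene order given by
    ``gene_ids`` (defaulting to the genes' first appearance in
    ``cluster_params``).  All (gene, cluster) pairs are flattened and two
    records returned: (frequency vs NLL, size vs NLL).
    """
    if gene_ids is None:
        gene_ids = list(dict.fromkeys(cluster_params["gene"]))
    pos = {g: i for i, g in enumerate(gene_ids)}
    if len(cluster_params) < 3:
        raise ValueError("need at least 3 (gene, cluster) pairs")
    nll_vals = np.array([
        mean_nll[int(c)].iloc[pos[g]]
        for g, c in zip(cluster_params["gene"], cluster_params["cluster"])
    ])
    freq = cluster_params["burst_frequency"].to_numpy(dtype=float)
    size = cluster_params["burst_size"].to_numpy(dtype=float)
    rec_f = pearson_with_t(freq, nll_vals, name="burst_frequency_vs_nll",
                           p_threshold=p_threshold)
    rec_s = pearson_with_t(size, nll_vals, name="burst_size_vs_nll",
                           p_threshold=p_threshold)
    return rec_f, rec_s


def cellwise_velocity_and_nll(
    velocity: np.ndarray, gene_cell_nll: np.ndarray
) -> VelocitySummary:
    """Per-cell velocity norm and mean NLL over the same gene panel.

    The cell-wise RNA velocity is the Euclidean norm of the per-gene velocity
    vector; the cell-wise NLL averages the per-gene NLL over the panel.
    """
    v = np.asarray(velocity, dtype=float)
    m = np.asarray(gene_cell_nll, dtype=float)
    if v.ndim != 2 or m.ndim != 2 or v.shape[0] != m.shape[0]:
        raise ValueError("velocity and NLL matrices must share cells")
    if m.shape[1] < 1:
        raise ValueError("gene panel must be non-empty")
    return VelocitySummary(
        velocity_norm=np.sqrt((v**2).sum(axis=1)),
        mean_nll=m.mean(axis=1),
    )


def lagged_cross_correlation(
    series_a: np.ndarray,
    series_b: np.ndarray,
    max_lag_bins: int = 5,
) -> tuple[int, pd.DataFrame]:
    """Cross-correlation of two binned series over integer lags.

    For each lag L in [-max_lag, +max_lag] the Pearson correlation of the
    truncated overlap of ``series_a`` with ``series_b`` shifted by L is
    computed; lags whose overlap is shorter than 3 points are skipped.  The
    best lag maximises r; a positive best lag means ``series_a`` leads
    ``series_b``.
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("series must be 1-D and of equal length")
    n = a.size
    if n <= max_lag_bins:
        raise ValueError("series must be longer than max_lag_bins")
    rows = []
    for lag in range(-max_lag_bins, max_lag_bins + 1):
        if lag >= 0:
            aa, bb = a[: n - lag], b[lag:]
        else:
            aa, bb = a[-lag:], b[: n + lag]
        if aa.size < 3 or np.std(aa) == 0 or np.std(bb) == 0:
            continue
        r = float(np.corrcoef(aa, bb)[0, 1])
        rows.append({"lag": lag, "r": r, "overlap": aa.size})
    if not rows:
        raise ValueError("no lag had a usable overlap")
    profile = pd.DataFrame(rows)
    best = int(profile.loc[profile["r"].idxmax(), "lag"])
    return best, profile


def bin_series_by_pseudotime(
    pseudotime: np.ndarray,
    values: np.ndarray,
    n_bins: int = 20,
) -> np.ndarray:
    """Mean of ``values`` in equal-count pseudotime bins (sorted order)."""
    order = np.argsort(pseudotime, kind="stable")
    v = np.asarray(values, dtype=float)[order]
    chunks = np.array_split(v, n_bins)
    return np.array([c.mean() for c in chunks if c.size > 0])
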