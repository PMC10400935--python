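"""End-to-end orchestration: preprocess -> cluster -> lineage -> uncertainty -> stats.

``run_pipeline`` executes every stage on an expression matrix, writes all
tabular outputs as headered CSV plus a JSON manifest recording the config
hash, the master seed, library versions and output checksums.  Re-running
with an identical config and inputs reproduces identical files; partial
outputs are removed if any stage fails.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cluster import (
    ClusteringResult,
    TelegraphClustering,
    _fit_cluster_params,
    _validate_counts,
)
from .config import RunConfig
from .io import ExpressionMatrix
from .lineage import LineageInference
from .preprocess import (
    filter_cells,
    filter_genes,
    normalize_counts,
    select_variable_genes,
)
from .stats import (
    bin_series_by_pseudotime,
    burst_uncertainty_table,
    cellwise_velocity_and_nll,
    lagged_cross_correlation,
)
from .telegraph import ParamGrid
from .uncertainty import (
    embed_2d,
    high_uncertainty_genes,
    landscape_surface,
    mean_gene_cluster_nll,
    moving_average_nll,
)

logger = logging.getLogger("burstscape")


@dataclass
class PipelineResult:
    """In-memory bundle of everything the pipeline computed."""

    matrix: ExpressionMatrix
    clustering: ClusteringResult
    lineage: LineageInference
    mean_nll: pd.DataFrame
    moving_averages: pd.DataFrame
    high_uncertainty: dict[int, list[str]]
    embedding: np.ndarray
    surface: object
    correlations: pd.DataFrame | None = None
    velocity_summary: pd.DataFrame | None = None
    velocity_lag: int | None = None
    lag_profile: pd.DataFrame | None = None
    output_files: list[str] = field(default_factory=list)


def _external_labels_result(
    X: np.ndarray, labels: np.ndarray, grid: ParamGrid
) -> ClusteringResult:
    labels = np.asarray(labels, dtype=int)
    ks = sorted(int(k) for k in np.unique(labels))
    if ks != list(range(1, len(ks) + 1)):
        remap = {k: i + 1 for i, k in enumerate(ks)}
        labels = np.array([remap[k] for k in labels])
    K = int(labels.max())
    X = _validate_counts(X, grid)
    param_index = _fit_cluster_params(X, labels, K, grid)
    from .cluster import _cell_cluster_loglik

    ll = _cell_cluster_loglik(X, param_index, grid)
    total = float(ll[np.arange(X.shape[0]), labels - 1].sum())
    return ClusteringResult(
        labels=labels, param_index=param_index, grid=grid,
        total_log_likelihood=total, n_clusters=K)


def run_pipeline(
    config: RunConfig,
    matrix: ExpressionMatrix,
    out_dir: str | Path,
    velocity: np.ndarray | None = None,
    labels: np.ndarray | None = None,
    grid: ParamGrid | None = None,
) -> PipelineResult:
    """Run every stage and write the result bundle under ``out_dir``.

    Parameters
    ----------
    config : RunConfig
        Flat configuration; ``seed`` drives all stochastic stages.
    matrix : ExpressionMatrix
        Raw cells x genes expression (any non-negative scale).
    velocity : ndarray, optional
        Precomputed cells x genes RNA-velocity matrix aligned with ``matrix``
        (before filtering); enables the velocity-vs-uncertainty comparison.
    labels : ndarray, optional
        Precomputed 1-based cluster labels; skips consensus clustering.
    grid : ParamGrid, optional
        Reuse an already-built fitting grid (otherwise built from config).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        return _run(config, matrix, out, velocity, labels, grid, written)
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise


def _write(df: pd.DataFrame, path: Path, written: list[Path], **kw) -> None:
    df.to_csv(path, index=False, **kw)
    written.append(path)


def _run(config, matrix, out, velocity, labels, grid, written):
    seed = int(config["seed"])
    logger.info("input: %d cells x %d genes", matrix.n_cells, matrix.n_genes)

    # --- preprocess -------------------------------------------------------
    m = normalize_counts(matrix, int(config["preprocess.m_max"]))
    keep_cells = np.ones(m.n_cells, dtype=bool)
    before = m.n_cells
    m2 = filter_cells(m, float(config["preprocess.min_fraction_expressed"]))
    keep_cells = np.isin(np.asarray(m.cell_ids), np.asarray(m2.cell_ids))
    logger.info("cell filter: %d -> %d cells", before, m2.n_cells)
    before_g = m2.n_genes
    m2 = filter_genes(m2, float(config["preprocess.min_cell_fraction_nonzero"]))
    logger.info("gene filter: %d -> %d genes", before_g, m2.n_genes)
    n_var = int(config["preprocess.n_variable_genes"])
    if n_var:
        m2 = select_variable_genes(m2, min(n_var, m2.n_genes))
        logger.info("kept %d most variable genes", m2.n_genes)
    gene_keep = np.isin(np.asarray(m.gene_ids), np.asarray(m2.gene_ids))
    X = np.asarray(m2.values, dtype=np.int64)

    if velocity is not None:
        velocity = np.asarray(velocity, dtype=float)
        if velocity.shape != matrix.values.shape:
            raise ValueError("velocity matrix must align with the raw matrix")
        velocity = velocity[keep_cells][:, gene_keep]
    if labels is not None:
        labels = np.asarray(labels)[keep_cells]

    if grid is None:
        grid = ParamGrid.from_config(config.to_dict())

    # --- cluster ----------------------------------------------------------
    consensus_frame = None
    if labels is not None:
        clustering = _external_labels_result(X, labels, grid)
        logger.info("using %d external clusters", clustering.n_clusters)
    else:
        k_cfg = int(config["cluster.k"])
        est = TelegraphClustering(
            n_clusters=k_cfg if k_cfg else None,
            k_max=int(config["cluster.k_max"]),
            n_runs=int(config["cluster.n_runs"]),
            max_iter=int(config["cluster.max_iter"]),
            greedy_restarts=int(config["cluster.greedy_restarts"]),
            kmedoids_restarts=int(config["cluster.kmedoids_restarts"]),
            grid=grid,
            random_state=seed,
        ).fit(X)
        clustering = est.result_
        logger.info("K=%d, total log-likelihood %.2f",
                    est.n_clusters_, est.total_log_likelihood_)
        consensus_frame = pd.DataFrame(
            est.consensus_.counts, index=m2.cell_ids, columns=m2.cell_ids)

    _write(pd.DataFrame({"cell_id": m2.cell_ids,
                         "cluster": clustering.labels}),
           out / "labels.csv", written)
    params_frame = clustering.params_frame(gene_ids=m2.gene_ids)
    _write(params_frame, out / "cluster_params.csv", written)
    if consensus_frame is not None:
        consensus_frame.to_csv(out / "consensus.csv")
        written.append(out / "consensus.csv")

    # --- lineage ----------------------------------------------------------
    root_cfg = int(config["lineage.root"])
    max_edges = int(config["lineage.max_edges"]) or None
    lin = LineageInference(
        s_grid_n=int(config["lineage.s_grid_n"]),
        root=root_cfg if root_cfg else None,
        max_edges=max_edges,
    ).fit(X, clustering, capture_time=m2.capture_time)
    logger.info("lineage edges: %s",
                sorted(tuple(e) for e in lin.graph_.graph.edges))
    _write(lin.graph_.edges_frame(), out / "edges.csv", written)
    placements = lin.placements_.copy()
    placements.insert(0, "cell_id", m2.cell_ids)
    _write(placements[["cell_id", "k1", "k2", "s", "pseudotime", "nll"]],
           out / "placements.csv", written)

    # --- uncertainty ------------------------------------------------------
    gene_nll_frame = pd.DataFrame(lin.gene_cell_nll_, index=m2.cell_ids,
                                  columns=m2.gene_ids)
    gene_nll_frame.index.name = "cell_id"
    gene_nll_frame.to_csv(out / "gene_cell_nll.csv")
    written.append(out / "gene_cell_nll.csv")

    mean_nll = mean_gene_cluster_nll(lin.gene_cell_nll_, clustering.labels)
    mn = mean_nll.copy()
    mn.insert(0, "gene", m2.gene_ids)
    _write(mn, out / "mean_gene_cluster_nll.csv", written)

    ma_rows = []
    for path_nodes in lin.graph_.root_to_leaf_paths():
        on_path = np.isin(placements["k1"], path_nodes) \
            & np.isin(placements["k2"], path_nodes)
        sub = placements[on_path]
        ma = moving_average_nll(
            sub["pseudotime"].to_numpy(), sub["nll"].to_numpy(),
            window_fraction=float(config["uncertainty.window_fraction"]),
            cell_ids=list(sub["cell_id"]),
        )
        ma.insert(0, "path", "-".join(str(n) for n in path_nodes))
        ma_rows.append(ma)
    moving_frame = pd.concat(ma_rows, ignore_index=True)
    _write(moving_frame, out / "moving_average_nll.csv", written)

    hug = high_uncertainty_genes(
        lin.gene_cell_nll_, clustering.labels, gene_ids=m2.gene_ids,
        frac_cells=float(config["uncertainty.frac_cells"]),
        n_sd=float(config["uncertainty.n_sd"]),
    )
    hug_frame = pd.DataFrame(
        [{"cluster": k, "gene": g} for k in sorted(hug) for g in hug[k]],
        columns=["cluster", "gene"],
    )
    _write(hug_frame, out / "high_uncertainty_genes.csv", written)

    coords = embed_2d(X, method=str(config["embedding.method"]),
                      random_state=seed + 1)
    emb = pd.DataFrame({"cell_id": m2.cell_ids,
                        "x": coords[:, 0], "y": coords[:, 1]})
    _write(emb, out / "embedding.csv", written)
    surface = landscape_surface(
        coords, lin.nll_, grid_n=int(config["landscape.grid_n"]),
        smoothness=float(config["landscape.smoothness"]))
    _write(surface.grid_frame(), out / "landscape_grid.csv", written)

    # --- stats ------------------------------------------------------------
    rec_f, rec_s = burst_uncertainty_table(
        params_frame, mean_nll, gene_ids=m2.gene_ids,
        p_threshold=float(config["stats.p_threshold"]))
    corr_frame = pd.DataFrame([rec.__dict__ for rec in (rec_f, rec_s)])
    _write(corr_frame, out / "correlations.csv", written)

    velocity_summary = None
    best_lag = None
    lag_profile = None
    if velocity is not None:
        summary = cellwise_velocity_and_nll(velocity, lin.gene_cell_nll_)
        velocity_summary = summary.to_frame(
            cell_ids=m2.cell_ids, pseudotime=lin.pseudotime_)
        _write(velocity_summary, out / "velocity_summary.csv", written)
        n_bins = int(config["stats.n_bins"])
        va = bin_series_by_pseudotime(lin.pseudotime_, summary.velocity_norm,
                                      n_bins)
        nb = bin_series_by_pseudotime(lin.pseudotime_, summary.mean_nll,
                                      n_bins)
        best_lag, lag_profile = lagged_cross_correlation(
            va, nb, max_lag_bins=int(config["stats.max_lag_bins"]))
        _write(lag_profile, out / "velocity_nll_lag.csv", written)

    # --- manifest ---------------------------------------------------------
    import scipy
    import sklearn

    manifest = {
        "config": config.to_dict(),
        "config_sha256": config.sha256(),
        "seed": seed,
        "versions": {
            "burstscape": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
        },
        "outputs": {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(written)
        },
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    written.append(manifest_path)

    return PipelineResult(
        matrix=m2,
        clustering=clustering,
        lineage=lin,
        mean_nll=mean_nll,
        moving_averages=moving_frame,
        high_uncertainty=hug,
        embedding=coords,
        surface=surface,
        correlations=corr_frame,
        velocity_summary=velocity_summary,
        velocity_lag=best_lag,
        lag_profile=lag_profile,
        output_files=[str(p) for p in written],
    )
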