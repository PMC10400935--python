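"""Likelihood-based cell clustering under the telegraph model.

Cells are grouped so that the total cell log-likelihood — the sum over cells
of the joint log-probability of their gene counts under per-cluster telegraph
parameters — is maximised.  A greedy coordinate ascent (refit per-cluster
per-gene maximum-likelihood parameters, then reassign each cell to its best
cluster) is repeated from many seeded starts; the co-assignment counts form a
consensus matrix which k-medoids converts into the final partition.  The
number of clusters can be chosen with the eigengap heuristic on the consensus
similarity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin

from .telegraph import ParamGrid, TelegraphParams, burst_frequency, burst_size

__all__ = [
    "ClusteringResult",
    "ConsensusMatrix",
    "cell_log_likelihood",
    "greedy_cluster",
    "consensus",
    "finalize_kmedoids",
    "eigengap_k",
    "TelegraphClustering",
]


@dataclass
class ClusteringResult:
    """Cell labels (1..K) with fitted per-(gene, cluster) telegraph parameters."""

    labels: np.ndarray
    param_index: np.ndarray  # (K, G) flat indices into the fitting grid
    grid: ParamGrid
    total_log_likelihood: float
    n_clusters: int
    objective_trace: list[float] = field(default_factory=list)

    def params(self, cluster: int, gene: int) -> TelegraphParams:
        """Fitted parameters of gene ``gene`` (0-based) in cluster (1-based)."""
        return self.grid.params_at(int(self.param_index[cluster - 1, gene]))

    def params_frame(self, gene_ids: list[str] | None = None) -> pd.DataFrame:
        """Long-format table of fitted rates and burst statistics."""
        K, G = self.param_index.shape
        if gene_ids is None:
            gene_ids = [f"gene_{g}" for g in range(G)]
        rows = []
        for k in range(1, K + 1):
            for g in range(G):
                p = self.params(k, g)
                rows.append(
                    {
                        "gene": gene_ids[g],
                        "cluster": k,
                        "theta_on": p.theta_on,
                        "theta_off": p.theta_off,
                        "theta_t": p.theta_t,
                        "burst_size": burst_size(p),
                        "burst_frequency": burst_frequency(p),
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class ConsensusMatrix:
    """Co-clustering counts over repeated greedy runs."""

    counts: np.ndarray
    n_runs: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("consensus counts must be square")

    @property
    def similarity(self) -> np.ndarray:
        """Fraction of runs in which two cells share a cluster."""
        return self.counts / float(self.n_runs)

    @property
    def dissimilarity(self) -> np.ndarray:
        return 1.0 - self.similarity


# ---------------------------------------------------------------------------
# Likelihood machinery (vectorised over cells, genes and grid points)


def _validate_counts(X: np.ndarray, grid: ParamGrid) -> np.ndarray:
    X = np.asarray(X)
    if X.ndim != 2:
        raise ValueError("expected a 2-D cells x genes count matrix")
    if not np.issubdtype(X.dtype, np.integer):
        if not np.allclose(X, np.round(X)):
            raise ValueError("counts must be integers; run normalize_counts")
        X = np.round(X).astype(np.int64)
    if X.min() < 0 or X.max() > grid.m_max:
        raise ValueError(f"counts outside the grid support 0..{grid.m_max}")
    return X.astype(np.int64)


def _fit_cluster_params(
    X: np.ndarray, labels: np.ndarray, K: int, grid: ParamGrid
) -> np.ndarray:
    """Per-(cluster, gene) grid MLE; returns flat grid indices, shape (K, G)."""
    N, G = X.shape
    hist = np.zeros((K * G, grid.m_max + 1))
    kg = (labels - 1)[:, None] * G + np.arange(G)[None, :]
    np.add.at(hist, (kg.ravel(), X.ravel()), 1.0)
    ll = grid.log_pmf @ hist.T  # (P, K*G)
    return np.argmax(ll, axis=0).reshape(K, G)


def _cell_cluster_loglik(
    X: np.ndarray, param_index: np.ndarray, grid: ParamGrid
) -> np.ndarray:
    """Log-likelihood of each cell under each cluster's parameters, (N, K)."""
    N, G = X.shape
    K = param_index.shape[0]
    out = np.empty((N, K))
    cols = np.arange(G)
    for k in range(K):
        M = grid.log_pmf[param_index[k]]  # (G, m_max+1)
        out[:, k] = M[cols[None, :], X].sum(axis=1)
    return out


def cell_log_likelihood(
    counts: np.ndarray,
    cluster_params: list[TelegraphParams],
    grid: ParamGrid,
) -> float:
    """Joint log-likelihood of one cell's counts under per-gene parameters.

    The cell likelihood is the product of the per-gene stationary
    probabilities, so its log is ``sum_g log P(m_g | theta_g)``; always <= 0.
    """
    counts = np.asarray(counts)
    if counts.ndim != 1:
        raise ValueError("counts must be a 1-D per-gene vector")
    if len(cluster_params) != counts.size:
        raise ValueError("one TelegraphParams per gene is required")
    total = 0.0
    for m, p in zip(counts, cluster_params):
        if m < 0 or m > grid.m_max:
            raise ValueError(f"count {m} outside the grid support")
        prob = grid.pmf_for(p)[int(m)]
        total += float(np.log(np.maximum(prob, 1e-300)))
    return total


def _repair_empty_clusters(
    labels: np.ndarray, assigned_ll: np.ndarray, K: int
) -> np.ndarray:
    """Move the globally worst-fitting cell into each empty cluster."""
    labels = labels.copy()
    for k in range(1, K + 1):
        if np.any(labels == k):
            continue
        sizes = np.bincount(labels, minlength=K + 1)
        movable = sizes[labels] > 1
        order = np.argsort(assigned_ll, kind="stable")
        worst = next(int(i) for i in order if movable[i])
        labels[worst] = k
    return labels


def _greedy_once(
    X: np.ndarray, n_clusters: int, grid: ParamGrid,
    rng: np.random.Generator, max_iter: int,
) -> ClusteringResult:
    N = X.shape[0]
    # random seed cells anchor the initial partition; a balanced random
    # labelling makes every cluster fit the same pooled mixture and the
    # ascent cannot break the symmetry
    seeds = rng.choice(N, size=n_clusters, replace=False)
    dist = np.abs(X[:, None, :] - X[seeds][None, :, :]).sum(axis=2)
    labels = np.argmin(dist, axis=1) + 1
    labels = _repair_empty_clusters(
        labels, -dist[np.arange(N), labels - 1].astype(float), n_clusters)
    trace: list[float] = []
    param_index = None
    for _ in range(max_iter):
        param_index = _fit_cluster_params(X, labels, n_clusters, grid)
        ll = _cell_cluster_loglik(X, param_index, grid)
        trace.append(float(ll[np.arange(N), labels - 1].sum()))
        new_labels = np.argmax(ll, axis=1) + 1
        new_labels = _repair_empty_clusters(
            new_labels, ll[np.arange(N), new_labels - 1], n_clusters)
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
    if any(b < a - 1e-8 * max(1.0, abs(a))
           for a, b in zip(trace, trace[1:])):
        raise AssertionError("greedy objective decreased; this is a bug")
    return ClusteringResult(
        labels=labels,
        param_index=param_index,
        grid=grid,
        total_log_likelihood=trace[-1],
        n_clusters=n_clusters,
        objective_trace=trace,
    )


def greedy_cluster(
    X: np.ndarray,
    n_clusters: int,
    grid: ParamGrid,
    seed: int | np.random.Generator = 0,
    max_iter: int = 100,
    n_init: int = 10,
) -> ClusteringResult:
    """Greedy maximisation of the total cell likelihood.

    Each start draws a seeded random balanced partition and alternates
    (a) refitting the per-cluster per-gene grid MLE and (b) batch-reassigning
    every cell to its maximum-likelihood cluster, until the labels stabilise
    — coordinate ascent, so the objective trace is non-decreasing (asserted).
    Clusters emptied by reassignment are repaired by moving in the globally
    worst-fitting cell, which cannot decrease the objective once the cluster
    is refit.  Because the ascent only finds a local optimum, ``n_init``
    restarts are run and the partition with the best final objective is kept.
    """
    X = _validate_counts(X, grid)
    N = X.shape[0]
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    if n_clusters > N:
        raise ValueError(f"n_clusters={n_clusters} exceeds {N} cells")
    if n_init < 1:
        raise ValueError("n_init must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    best: ClusteringResult | None = None
    for _ in range(n_init):
        result = _greedy_once(X, n_clusters, grid, rng, max_iter)
        if best is None or result.total_log_likelihood \
                > best.total_log_likelihood:
            best = result
    return best


def consensus(
    X: np.ndarray,
    n_clusters: int,
    grid: ParamGrid,
    n_runs: int = 50,
    seed: int = 0,
    max_iter: int = 100,
    n_init: int = 10,
) -> ConsensusMatrix:
    """Co-clustering counts over ``n_runs`` greedy runs with derived seeds."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    X = _validate_counts(X, grid)
    N = X.shape[0]
    counts = np.zeros((N, N), dtype=np.int64)
    for child in np.random.SeedSequence(seed).spawn(n_runs):
        rng = np.random.default_rng(child)
        res = greedy_cluster(X, n_clusters, grid, seed=rng,
                             max_iter=max_iter, n_init=n_init)
        same = res.labels[:, None] == res.labels[None, :]
        counts += same
    return ConsensusMatrix(counts=counts, n_runs=n_runs)


# ---------------------------------------------------------------------------
# k-medoids on the consensus dissimilarity


def _kmedoids_once(
    D: np.ndarray, K: int, rng: np.random.Generator, max_iter: int = 100
) -> tuple[np.ndarray, float]:
    N = D.shape[0]
    # k-medoids++-style spread initialisation on the dissimilarity
    medoids = [int(rng.integers(N))]
    while len(medoids) < K:
        d_min = D[:, medoids].min(axis=1)
        w = d_min**2
        if w.sum() <= 0:
            remaining = [i for i in range(N) if i not in medoids]
            medoids.append(int(rng.choice(remaining)))
            continue
        medoids.append(int(rng.choice(N, p=w / w.sum())))
    medoids = np.asarray(sorted(medoids))
    for _ in range(max_iter):
        assign = np.argmin(D[:, medoids], axis=1)
        new_medoids = medoids.copy()
        for k in range(K):
            members = np.flatnonzero(assign == k)
            if members.size == 0:
                continue
            within = D[np.ix_(members, members)].sum(axis=1)
            new_medoids[k] = members[int(np.argmin(within))]
        new_medoids = np.sort(new_medoids)
        if np.array_equal(new_medoids, medoids):
            break
        medoids = new_medoids
    assign = np.argmin(D[:, medoids], axis=1)
    cost = float(D[np.arange(N), medoids[assign]].sum())
    return assign + 1, cost


def finalize_kmedoids(
    consensus_matrix: ConsensusMatrix,
    n_clusters: int,
    seed: int = 0,
    X: np.ndarray | None = None,
    grid: ParamGrid | None = None,
    n_restarts: int = 20,
) -> ClusteringResult:
    """Final partition: k-medoids on 1 - consensus/n_runs, then parameter refit.

    The best of ``n_restarts`` seeded runs (lowest total within-cluster
    dissimilarity) is kept.  When counts and a grid are supplied, per-cluster
    per-gene parameters are refit by the grid MLE and the total log-likelihood
    recomputed; otherwise the result carries labels only.
    """
    D = consensus_matrix.dissimilarity.copy()
    np.fill_diagonal(D, 0.0)
    N = D.shape[0]
    if n_clusters > N:
        raise ValueError("n_clusters exceeds the number of cells")
    off = D[~np.eye(N, dtype=bool)]
    rng = np.random.default_rng(seed)
    if n_clusters > 1 and off.size and np.allclose(off, off.flat[0]):
        warnings.warn(
            "consensus is uninformative (all pairs equally dissimilar); "
            "returning a seeded arbitrary split",
            stacklevel=2,
        )
        labels = rng.permutation(N) % n_clusters + 1
    else:
        best_labels, best_cost = None, np.inf
        for _ in range(n_restarts):
            labels_r, cost = _kmedoids_once(D, n_clusters, rng)
            if cost < best_cost - 1e-12:
                best_labels, best_cost = labels_r, cost
        labels = best_labels
    if X is None or grid is None:
        return ClusteringResult(
            labels=labels,
            param_index=np.zeros((n_clusters, 0), dtype=int),
            grid=grid if grid is not None else ParamGrid(
                np.array([1.0]), np.array([1.0]), np.array([1.0]), m_max=1),
            total_log_likelihood=float("nan"),
            n_clusters=n_clusters,
        )
    X = _validate_counts(X, grid)
    param_index = _fit_cluster_params(X, labels, n_clusters, grid)
    ll = _cell_cluster_loglik(X, param_index, grid)
    total = float(ll[np.arange(X.shape[0]), labels - 1].sum())
    return ClusteringResult(
        labels=labels,
        param_index=param_index,
        grid=grid,
        total_log_likelihood=total,
        n_clusters=n_clusters,
    )


def eigengap_k(consensus_matrix: ConsensusMatrix, k_max: int = 10) -> int:
    """Choose K by the eigengap of the consensus similarity's Laplacian.

    Computes the symmetric normalised Laplacian of the co-clustering
    similarity and returns the K in 2..k_max with the largest gap between
    consecutive eigenvalues.  A disconnected similarity graph short-circuits
    to its number of components; a gapless (uninformative) spectrum returns 2
    with a warning.
    """
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    S = consensus_matrix.similarity
    S = 0.5 * (S + S.T)
    import scipy.sparse.csgraph as csgraph

    n_comp, _ = csgraph.connected_components(S > 0, directed=False)
    if n_comp > 1:
        if n_comp <= k_max:
            return int(n_comp)
        warnings.warn(
            f"similarity graph has {n_comp} components > k_max; "
            "returning k_max", stacklevel=2)
        return int(k_max)
    deg = S.sum(axis=1)
    d = 1.0 / np.sqrt(np.maximum(deg, 1e-300))
    L = np.eye(S.shape[0]) - d[:, None] * S * d[None, :]
    eigvals = np.linalg.eigvalsh(L)
    k_hi = min(k_max, S.shape[0] - 1)
    gaps = np.array([eigvals[k] - eigvals[k - 1] for k in range(2, k_hi + 1)])
    if gaps.size == 0 or gaps.max() < 1e-12:
        warnings.warn(
            "no eigengap in the consensus spectrum; returning K=2",
            stacklevel=2)
        return 2
    return int(np.argmax(gaps)) + 2


# ---------------------------------------------------------------------------
# Estimator


class TelegraphClustering(ClusterMixin, BaseEstimator):
    """Consensus clustering of cells by telegraph-model likelihood.

    Scikit-learn style estimator: ``fit(X)`` on an integer cells x genes count
    matrix runs ``n_runs`` greedy likelihood maximisations, aggregates them
    into a consensus matrix, and finalises labels with k-medoids.  When
    ``n_clusters`` is None the number of clusters is picked by the eigengap
    heuristic on a consensus built at ``k_max``.

    Parameters
    ----------
    n_clusters : int or None
        Number of clusters; None triggers eigengap selection up to ``k_max``.
    k_max : int
        Largest K considered when ``n_clusters`` is None.
    n_runs : int
        Greedy runs aggregated into the consensus matrix.
    max_iter : int
        Cap on greedy coordinate-ascent sweeps per run.
    greedy_restarts : int
        Random restarts inside each greedy run (best objective kept).
    kmedoids_restarts : int
        Seeded k-medoids restarts on the consensus dissimilarity.
    grid : ParamGrid or None
        Fitting grid; the default grid is built lazily when None.
    random_state : int
        Master seed for initial partitions and k-medoids.

    Attributes
    ----------
    labels_ : ndarray of int
        Cluster label (1..K) per cell.
    consensus_ : ConsensusMatrix
    result_ : ClusteringResult
        Labels plus fitted per-(gene, cluster) parameters.
    n_clusters_ : int
    """

    def __init__(
        self,
        n_clusters: int | None = None,
        k_max: int = 10,
        n_runs: int = 50,
        max_iter: int = 100,
        greedy_restarts: int = 10,
        kmedoids_restarts: int = 20,
        grid: ParamGrid | None = None,
        random_state: int = 0,
    ) -> None:
        self.n_clusters = n_clusters
        self.k_max = k_max
        self.n_runs = n_runs
        self.max_iter = max_iter
        self.greedy_restarts = greedy_restarts
        self.kmedoids_restarts = kmedoids_restarts
        self.grid = grid
        self.random_state = random_state

    def fit(self, X, y=None):
        grid = self.grid if self.grid is not None else ParamGrid.default()
        X = _validate_counts(np.asarray(X), grid)
        k = self.n_clusters
        if k is None:
            probe = consensus(X, self.k_max, grid, n_runs=self.n_runs,
                              seed=self.random_state, max_iter=self.max_iter,
                              n_init=self.greedy_restarts)
            k = eigengap_k(probe, k_max=self.k_max)
        cons = consensus(X, k, grid, n_runs=self.n_runs,
                         seed=self.random_state, max_iter=self.max_iter,
                         n_init=self.greedy_restarts)
        result = finalize_kmedoids(
            cons, k, seed=self.random_state, X=X, grid=grid,
            n_restarts=self.kmedoids_restarts)
        self.grid_ = grid
        self.consensus_ = cons
        self.result_ = result
        self.labels_ = result.labels
        self.n_clusters_ = k
        self.total_log_likelihood_ = result.total_log_likelihood
        return self
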