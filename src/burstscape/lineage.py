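"""Lineage-progression inference and per-cell placement along transitions.

Cluster distance is a likelihood drop: the mean, over the cells of two
clusters, of the decrease in cell log-likelihood incurred when both clusters
are refit as one.  Edges between clusters are added in ascending distance
until the cluster graph is connected.  Each cell is then placed on the
adjacent edge and fractional position ``s`` maximising its interpolated
likelihood, obtained by blending the two endpoint clusters' mRNA
distributions gene-wise: ``(1-s) P_k1,g + s P_k2,g``.  The cell's
transcriptional uncertainty is the negative log of this maximal likelihood,
and its pseudotime linearly interpolates the endpoint clusters' pseudotimes
at ``s``.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .cluster import ClusteringResult, _fit_cluster_params, _validate_counts
from .telegraph import ParamGrid

__all__ = [
    "LineageGraph",
    "CellPlacement",
    "cluster_distance",
    "pairwise_cluster_distances",
    "build_lineage",
    "place_cell",
    "place_cells",
    "cell_pseudotime",
    "LineageInference",
]


@dataclass
class LineageGraph:
    """Undirected cluster-level transition graph with root-anchored pseudotimes.

    ``pseudotime`` maps each cluster to a value in [0, 1]: the root is 0 and
    graph-hop depth is scaled so the deepest leaf is 1.
    """

    graph: nx.Graph
    root: int
    pseudotime: dict[int, float]
    distances: dict[tuple[int, int], float]

    def oriented_edges(self) -> list[tuple[int, int]]:
        """Edges oriented root-ward first (smaller pseudotime, then index)."""
        out = []
        for a, b in self.graph.edges:
            ta, tb = self.pseudotime[a], self.pseudotime[b]
            if (tb, b) < (ta, a):
                a, b = b, a
            out.append((a, b))
        return sorted(out)

    def root_to_leaf_paths(self) -> list[list[int]]:
        leaves = [n for n in self.graph.nodes
                  if self.graph.degree[n] == 1 and n != self.root]
        return [nx.shortest_path(self.graph, self.root, leaf)
                for leaf in sorted(leaves)]

    def edges_frame(self) -> pd.DataFrame:
        in_graph = {tuple(sorted(e)) for e in self.graph.edges}
        rows = [
            {"k1": k1, "k2": k2, "distance": d,
             "in_graph": tuple(sorted((k1, k2))) in in_graph}
            for (k1, k2), d in sorted(self.distances.items())
        ]
        return pd.DataFrame(rows)


@dataclass
class CellPlacement:
    """One cell's optimal position on the lineage graph."""

    edge: tuple[int, int]
    s: float
    log_likelihood: float
    nll: float
    pseudotime: float
    gene_nll: np.ndarray


def _own_and_pooled_loglik(
    X: np.ndarray,
    labels: np.ndarray,
    k1: int,
    k2: int,
    grid: ParamGrid,
) -> tuple[np.ndarray, np.ndarray]:
    members = np.flatnonzero((labels == k1) | (labels == k2))
    Xu = X[members]
    lab = labels[members]
    G = X.shape[1]
    cols = np.arange(G)
    own = np.empty(members.size)
    for k in (k1, k2):
        sub = lab == k
        idx = _fit_cluster_params(Xu[sub], np.ones(sub.sum(), dtype=int),
                                  1, grid)[0]
        M = grid.log_pmf[idx]
        own[sub] = M[cols[None, :], Xu[sub]].sum(axis=1)
    pooled_idx = _fit_cluster_params(
        Xu, np.ones(members.size, dtype=int), 1, grid)[0]
    Mp = grid.log_pmf[pooled_idx]
    pooled = Mp[cols[None, :], Xu].sum(axis=1)
    return own, pooled


def cluster_distance(
    X: np.ndarray,
    labels: np.ndarray,
    k1: int,
    k2: int,
    grid: ParamGrid,
) -> float:
    """Mean per-cell log-likelihood drop from merging two clusters.

    Both clusters' cells are refit as a single pooled cluster (per-gene grid
    MLE) and the distance is the average of (own-cluster log-likelihood minus
    pooled log-likelihood) over the union — non-negative up to grid
    resolution, and symmetric in the pair.
    """
    if k1 == k2:
        raise ValueError("cluster distance needs two distinct clusters")
    X = _validate_counts(X, grid)
    labels = np.asarray(labels)
    for k in (k1, k2):
        if not np.any(labels == k):
            raise ValueError(f"cluster {k} is empty")
    own, pooled = _own_and_pooled_loglik(X, labels, k1, k2, grid)
    return float(np.mean(own - pooled))


def pairwise_cluster_distances(
    X: np.ndarray, labels: np.ndarray, grid: ParamGrid
) -> dict[tuple[int, int], float]:
    ks = sorted(int(k) for k in np.unique(labels))
    out = {}
    for i, k1 in enumerate(ks):
        for k2 in ks[i + 1:]:
            out[(k1, k2)] = cluster_distance(X, labels, k1, k2, grid)
    return out


def build_lineage(
    distances: dict[tuple[int, int], float],
    n_clusters: int,
    max_edges: int | None = None,
    root: int | None = None,
    cluster_capture_time: dict[int, float] | None = None,
) -> LineageGraph:
    """Connect clusters by ascending distance; anchor pseudotime at a root.

    Edges are added in increasing distance (ties by cluster-index pair) until
    every cluster is connected; ``max_edges`` may extend the graph further.
    The root is given explicitly or chosen as the cluster with the smallest
    mean capture time; cluster pseudotime is graph-hop depth from the root
    scaled so the deepest leaf sits at 1.
    """
    clusters = list(range(1, n_clusters + 1))
    expected = {(a, b) for i, a in enumerate(clusters) for b in clusters[i + 1:]}
    got = {tuple(sorted(k)) for k in distances}
    if got != expected:
        raise ValueError("all pairwise cluster distances are required")
    g = nx.Graph()
    g.add_nodes_from(clusters)
    ordered = sorted(distances.items(), key=lambda kv: (kv[1], kv[0]))
    n_added = 0
    # ascending-distance edge addition; edges closing a cycle are skipped
    # while connecting (lineages are acyclic), so the connected result is
    # the minimum spanning tree of the cluster distances
    for (k1, k2), d in ordered:
        if nx.is_connected(g):
            break
        if nx.has_path(g, k1, k2):
            continue
        g.add_edge(k1, k2, distance=d)
        n_added += 1
    if max_edges is not None and max_edges > n_added:
        for (k1, k2), d in ordered:
            if n_added >= max_edges:
                break
            if not g.has_edge(k1, k2):
                g.add_edge(k1, k2, distance=d)
                n_added += 1
    if root is None:
        if cluster_capture_time is None:
            raise ValueError(
                "specify a root cluster or provide capture times")
        root = min(clusters, key=lambda k: (cluster_capture_time[k], k))
    depth = nx.single_source_shortest_path_length(g, root)
    max_depth = max(depth.values())
    pseudo = {k: (depth[k] / max_depth if max_depth > 0 else 0.0)
              for k in clusters}
    return LineageGraph(graph=g, root=int(root), pseudotime=pseudo,
                        distances=dict(distances))


def place_cells(
    X: np.ndarray,
    graph: LineageGraph,
    result: ClusteringResult,
    s_grid: np.ndarray | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Optimal (edge, s) placement for every cell, plus per-gene NLLs.

    For each edge adjacent to a cell's cluster and each ``s`` on the grid,
    the per-gene probability is the mixture ``(1-s) P_k1,g(m) + s P_k2,g(m)``
    of the endpoint clusters' distributions; the placement maximises the
    summed log mixture probability.  Ties go to the lower edge (sorted
    root-ward orientation) and then to smaller ``s``.

    Returns a DataFrame (k1, k2, s, log_likelihood, nll, pseudotime) indexed
    like ``X`` rows, and the (n_cells, n_genes) per-gene NLL matrix at each
    cell's optimum, whose rows sum to the cell NLLs.
    """
    grid = result.grid
    X = _validate_counts(X, grid)
    if s_grid is None:
        s_grid = np.linspace(0.0, 1.0, 21)
    N, G = X.shape
    cols = np.arange(G)
    labels = result.labels
    best_ll = np.full(N, -np.inf)
    best_edge = np.zeros((N, 2), dtype=int)
    best_s = np.zeros(N)
    edges = graph.oriented_edges()
    for k1, k2 in edges:
        cells = np.flatnonzero((labels == k1) | (labels == k2))
        if cells.size == 0:
            continue
        P1 = grid.pmf[result.param_index[k1 - 1]]
        P2 = grid.pmf[result.param_index[k2 - 1]]
        Xc = X[cells]
        for s in s_grid:
            mix = (1.0 - s) * P1 + s * P2
            probs = mix[cols[None, :], Xc]
            if np.any(probs <= 0):
                raise ValueError(
                    "zero mixture probability for an observed count; "
                    "increase m_max")
            ll = np.log(probs).sum(axis=1)
            upd = ll > best_ll[cells]
            upd_idx = cells[upd]
            best_ll[upd_idx] = ll[upd]
            best_edge[upd_idx] = (k1, k2)
            best_s[upd_idx] = s
    if np.any(np.isinf(best_ll)):
        raise ValueError("some cells' clusters have no adjacent edge")
    gene_nll = np.empty((N, G))
    for (k1, k2) in edges:
        for s in np.unique(best_s):
            sel = np.flatnonzero(
                (best_edge[:, 0] == k1) & (best_edge[:, 1] == k2)
                & (best_s == s))
            if sel.size == 0:
                continue
            P1 = grid.pmf[result.param_index[k1 - 1]]
            P2 = grid.pmf[result.param_index[k2 - 1]]
            mix = (1.0 - s) * P1 + s * P2
            gene_nll[sel] = -np.log(mix[cols[None, :], X[sel]])
    t1 = np.array([graph.pseudotime[k] for k in best_edge[:, 0]])
    t2 = np.array([graph.pseudotime[k] for k in best_edge[:, 1]])
    pseudotime = (1.0 - best_s) * t1 + best_s * t2
    frame = pd.DataFrame(
        {
            "k1": best_edge[:, 0],
            "k2": best_edge[:, 1],
            "s": best_s,
            "log_likelihood": best_ll,
            "nll": -best_ll,
            "pseudotime": pseudotime,
        }
    )
    return frame, gene_nll


def place_cell(
    counts: np.ndarray,
    graph: LineageGraph,
    result: ClusteringResult,
    label: int,
    s_grid: np.ndarray | None = None,
) -> CellPlacement:
    """Place a single cell; see :func:`place_cells`."""
    counts = np.atleast_2d(counts)
    one = ClusteringResult(
        labels=np.array([label]),
        param_index=result.param_index,
        grid=result.grid,
        total_log_likelihood=result.total_log_likelihood,
        n_clusters=result.n_clusters,
    )
    frame, gene_nll = place_cells(counts, graph, one, s_grid=s_grid)
    row = frame.iloc[0]
    return CellPlacement(
        edge=(int(row.k1), int(row.k2)),
        s=float(row.s),
        log_likelihood=float(row.log_likelihood),
        nll=float(row.nll),
        pseudotime=float(row.pseudotime),
        gene_nll=gene_nll[0],
    )


def cell_pseudotime(placement: CellPlacement, graph: LineageGraph) -> float:
    """Linear interpolation of the edge endpoints' cluster pseudotimes at s."""
    k1, k2 = placement.edge
    return (1.0 - placement.s) * graph.pseudotime[k1] \
        + placement.s * graph.pseudotime[k2]


class LineageInference:
    """Lineage graph, placements and pseudotimes from a clustering result.

    Parameters
    ----------
    s_grid_n : int
        Resolution of the fractional-position grid on each edge (default 21,
        i.e. steps of 0.05).
    root : int or None
        Root cluster; when None the cluster with the smallest mean capture
        time is used (capture times must then be supplied to ``fit``).
    max_edges : int or None
        Optionally extend the graph beyond minimal connectivity.

    Attributes
    ----------
    graph_ : LineageGraph
    placements_ : DataFrame with k1, k2, s, nll and pseudotime per cell
    gene_cell_nll_ : ndarray (n_cells, n_genes)
    pseudotime_ : ndarray
    nll_ : ndarray
    """

    def __init__(self, s_grid_n: int = 21, root: int | None = None,
                 max_edges: int | None = None) -> None:
        self.s_grid_n = s_grid_n
        self.root = root
        self.max_edges = max_edges

    def fit(self, X, clustering: ClusteringResult,
            capture_time: np.ndarray | None = None):
        X = _validate_counts(X, clustering.grid)
        distances = pairwise_cluster_distances(X, clustering.labels,
                                               clustering.grid)
        cluster_ct = None
        if capture_time is not None:
            capture_time = np.asarray(capture_time, dtype=float)
            cluster_ct = {
                int(k): float(capture_time[clustering.labels == k].mean())
                for k in np.unique(clustering.labels)
            }
        self.graph_ = build_lineage(
            distances, clustering.n_clusters, max_edges=self.max_edges,
            root=self.root, cluster_capture_time=cluster_ct)
        s_grid = np.linspace(0.0, 1.0, self.s_grid_n)
        self.placements_, self.gene_cell_nll_ = place_cells(
            X, self.graph_, clustering, s_grid=s_grid)
        self.pseudotime_ = self.placements_["pseudotime"].to_numpy()
        self.nll_ = self.placements_["nll"].to_numpy()
        return self
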