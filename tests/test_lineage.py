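import numpy as np
import pytest

from burstscape import (
    TelegraphParams,
    build_lineage,
    cell_pseudotime,
    cluster_distance,
    place_cell,
    place_cells,
    sample_stationary,
)
from burstscape.cluster import ClusteringResult, _fit_cluster_params
from burstscape.lineage import CellPlacement, LineageGraph


def sampled_clusters(theta_ts, n_per, grid, seed=0):
    """Counts for one gene with per-cluster transcription rates."""
    rng = np.random.default_rng(seed)
    cols = []
    for t in theta_ts:
        cols.append(sample_stationary(TelegraphParams(1, 1, t), n_per, rng))
    X = np.concatenate(cols)[:, None]
    X = np.clip(X, 0, grid.m_max)
    labels = np.repeat(np.arange(1, len(theta_ts) + 1), n_per)
    return X, labels


class TestClusterDistance:
    def test_identical_parameter_clusters_are_near_zero(self, small_grid):
        X, labels = sampled_clusters([20.0, 20.0], 150, small_grid, seed=1)
        d = cluster_distance(X, labels, 1, 2, small_grid)
        assert 0 <= d < 0.5

    def test_symmetric(self, small_grid):
        X, labels = sampled_clusters([5.0, 40.0], 80, small_grid, seed=2)
        assert cluster_distance(X, labels, 1, 2, small_grid) == \
            cluster_distance(X, labels, 2, 1, small_grid)

    def test_grows_with_planted_separation(self, small_grid):
        base = 4.0
        dists = []
        for factor in (2.0, 5.0, 20.0):
            X, labels = sampled_clusters([base, base * factor], 150,
                                         small_grid, seed=3)
            dists.append(cluster_distance(X, labels, 1, 2, small_grid))
        assert dists[0] < dists[1] < dists[2]

    def test_empty_cluster_rejected(self, small_grid):
        X, labels = sampled_clusters([5.0, 20.0], 10, small_grid)
        with pytest.raises(ValueError):
            cluster_distance(X, labels, 1, 3, small_grid)


class TestBuildLineage:
    def test_three_cluster_trace(self):
        d = {(1, 2): 1.0, (2, 3): 2.0, (1, 3): 5.0}
        g = build_lineage(d, 3, root=1)
        assert sorted(tuple(sorted(e)) for e in g.graph.edges) == \
            [(1, 2), (2, 3)]
        assert g.pseudotime == {1: 0.0, 2: 0.5, 3: 1.0}

    def test_always_connected(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            ks = range(1, 6)
            d = {(a, b): float(rng.random())
                 for i, a in enumerate(ks) for b in list(ks)[i + 1:]}
            g = build_lineage(d, 5, root=1)
            import networkx as nx

            assert nx.is_connected(g.graph)
            assert g.graph.number_of_edges() == 4  # spanning tree

    def test_root_from_capture_times(self):
        d = {(1, 2): 1.0, (2, 3): 2.0, (1, 3): 5.0}
        g = build_lineage(d, 3, cluster_capture_time={1: 9.0, 2: 0.0, 3: 4.0})
        assert g.root == 2
        assert g.pseudotime[2] == 0.0

    def test_missing_distances_rejected(self):
        with pytest.raises(ValueError):
            build_lineage({(1, 2): 1.0}, 3, root=1)

    def test_max_edges_extends_beyond_tree(self):
        d = {(1, 2): 1.0, (2, 3): 2.0, (1, 3): 5.0}
        g = build_lineage(d, 3, root=1, max_edges=3)
        assert g.graph.number_of_edges() == 3


def toy_result_and_graph(grid, theta_ts=(2.0, 15.0, 60.0), n_per=60,
                         seed=4):
    X, labels = sampled_clusters(theta_ts, n_per, grid, seed=seed)
    K = len(theta_ts)
    param_index = _fit_cluster_params(X, labels, K, grid)
    result = ClusteringResult(labels=labels, param_index=param_index,
                              grid=grid, total_log_likelihood=0.0,
                              n_clusters=K)
    d = {(a, b): abs(theta_ts[a - 1] - theta_ts[b - 1])
         for a in range(1, K + 1) for b in range(a + 1, K + 1)}
    graph = build_lineage(d, K, root=1)
    return X, result, graph


class TestPlacement:
    def test_endpoint_identity_at_s_zero(self, small_grid):
        X, result, graph = toy_result_and_graph(small_grid)
        frame, gene_nll = place_cells(X, graph, result,
                                      s_grid=np.array([0.0]))
        from burstscape.cluster import _cell_cluster_loglik

        ll = _cell_cluster_loglik(X, result.param_index, small_grid)
        # with s=0 only, every cell's placement equals an endpoint cluster
        for i in range(X.shape[0]):
            k1 = int(frame.loc[i, "k1"])
            assert frame.loc[i, "log_likelihood"] == pytest.approx(
                ll[i, k1 - 1], abs=1e-9)

    def test_nll_not_worse_than_either_endpoint(self, small_grid):
        X, result, graph = toy_result_and_graph(small_grid)
        frame, _ = place_cells(X, graph, result)
        from burstscape.cluster import _cell_cluster_loglik

        ll = _cell_cluster_loglik(X, result.param_index, small_grid)
        for i in range(X.shape[0]):
            k1, k2 = int(frame.loc[i, "k1"]), int(frame.loc[i, "k2"])
            best_endpoint = max(ll[i, k1 - 1], ll[i, k2 - 1])
            assert frame.loc[i, "log_likelihood"] >= best_endpoint - 1e-9

    def test_coarse_argmax_matches_fine_grid_oracle(self, small_grid):
        X, result, graph = toy_result_and_graph(small_grid, n_per=34)
        coarse = np.linspace(0, 1, 21)
        fine = np.linspace(0, 1, 201)
        f_coarse, _ = place_cells(X, graph, result, s_grid=coarse)
        f_fine, _ = place_cells(X, graph, result, s_grid=fine)
        same_edge = (f_coarse[["k1", "k2"]].to_numpy()
                     == f_fine[["k1", "k2"]].to_numpy()).all(axis=1)
        step = coarse[1] - coarse[0]
        diff = np.abs(f_coarse["s"].to_numpy() - f_fine["s"].to_numpy())
        assert np.all(diff[same_edge] <= step + 1e-12)

    def test_per_gene_nll_sums_to_cell_nll(self, small_grid):
        X, result, graph = toy_result_and_graph(small_grid)
        frame, gene_nll = place_cells(X, graph, result)
        assert np.allclose(gene_nll.sum(axis=1), frame["nll"], atol=1e-8)
        assert gene_nll.min() >= 0

    def test_single_cell_wrapper(self, small_grid):
        X, result, graph = toy_result_and_graph(small_grid)
        placement = place_cell(X[0], graph, result, label=1)
        assert placement.nll == pytest.approx(-placement.log_likelihood)
        assert 0.0 <= placement.s <= 1.0


class TestPseudotime:
    def make_graph(self):
        import networkx as nx

        g = nx.Graph([(1, 2)])
        return LineageGraph(graph=g, root=1,
                            pseudotime={1: 0.0, 2: 1.0},
                            distances={(1, 2): 1.0})

    def placement(self, s):
        return CellPlacement(edge=(1, 2), s=s, log_likelihood=-1.0, nll=1.0,
                             pseudotime=np.nan, gene_nll=np.zeros(1))

    def test_linear_interpolation(self):
        g = self.make_graph()
        assert cell_pseudotime(self.placement(0.3), g) == pytest.approx(0.3)
        assert cell_pseudotime(self.placement(0.0), g) == 0.0

    def test_monotone_in_s(self):
        g = self.make_graph()
        ts = [cell_pseudotime(self.placement(s), g)
              for s in np.linspace(0, 1, 11)]
        assert np.all(np.diff(ts) >= 0)
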