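import numpy as np
import pytest

from burstscape import (
    GridSurface,
    embed_2d,
    high_uncertainty_genes,
    landscape_surface,
    mean_gene_cluster_nll,
    moving_average_nll,
)


class TestMeanGeneClusterNll:
    def test_small_cluster_averages(self):
        nll = np.array([[1.0], [3.0], [7.0]])
        labels = np.array([1, 1, 2])
        out = mean_gene_cluster_nll(nll, labels)
        assert out.loc[0, 1] == 2.0
        assert out.loc[0, 2] == 7.0  # singleton cluster keeps its own NLL

    def test_matches_bruteforce_loop(self):
        rng = np.random.default_rng(0)
        nll = rng.random((6, 3))
        labels = np.array([1, 2, 1, 3, 2, 1])
        out = mean_gene_cluster_nll(nll, labels)
        for k in (1, 2, 3):
            for g in range(3):
                acc = [nll[n, g] for n in range(6) if labels[n] == k]
                assert out.loc[g, k] == pytest.approx(np.mean(acc))

    def test_label_length_mismatch(self):
        with pytest.raises(ValueError):
            mean_gene_cluster_nll(np.ones((4, 2)), np.array([1, 2]))


class TestMovingAverage:
    def test_constant_series_stays_constant(self):
        out = moving_average_nll(np.linspace(0, 1, 30), np.full(30, 2.5))
        assert np.allclose(out["nll"], 2.5)

    def test_window_length_is_ceil_fraction(self):
        out = moving_average_nll(np.linspace(0, 1, 100), np.arange(100.0),
                                 window_fraction=0.10)
        # window of 10 cells, stride 1 -> 91 windows
        assert len(out) == 91

    def test_matches_bruteforce_windowing(self):
        rng = np.random.default_rng(3)
        t = rng.random(23)
        y = rng.random(23)
        out = moving_average_nll(t, y, window_fraction=0.2)
        order = np.argsort(t, kind="stable")
        w = int(np.ceil(0.2 * 23))
        for i in range(23 - w + 1):
            sel = order[i:i + w]
            assert out.loc[i, "pseudotime"] == pytest.approx(t[sel].mean())
            assert out.loc[i, "nll"] == pytest.approx(y[sel].mean())

    def test_pseudotime_ties_broken_by_cell_id(self):
        t = np.zeros(4)
        y = np.array([4.0, 3.0, 2.0, 1.0])
        out = moving_average_nll(t, y, window_fraction=0.25,
                                 cell_ids=["d", "c", "b", "a"])
        assert list(out["nll"]) == [1.0, 2.0, 3.0, 4.0]


class TestHighUncertaintyGenes:
    def test_degenerate_equal_matrix_selects_nothing(self):
        out = high_uncertainty_genes(np.full((10, 4), 3.0),
                                     np.repeat([1, 2], 5))
        assert all(len(v) == 0 for v in out.values())

    def test_constructed_selection(self):
        # gene 0 exceeds the 3-SD threshold in 40% of cluster-1 cells;
        # the exceedances are rare overall so the threshold stays low
        nll = np.zeros((100, 10))
        nll[:4, 0] = 50.0  # 4 of the 10 cells in cluster 1
        labels = np.array([1] * 10 + [2] * 90)
        delta = nll.mean() + 3 * nll.std()
        exceed = (nll[labels == 1] > delta).sum(axis=0)
        expected = [f"g{g}" for g in range(10) if exceed[g] >= 0.3 * 10]
        out = high_uncertainty_genes(
            nll, labels, gene_ids=[f"g{g}" for g in range(10)])
        assert out[1] == expected == ["g0"]
        assert out[2] == []

    def test_zero_fraction_includes_any_exceedance(self):
        nll = np.zeros((6, 1))
        nll[0, 0] = 10.0
        out = high_uncertainty_genes(nll, np.ones(6, dtype=int),
                                     gene_ids=["g"], frac_cells=0.0,
                                     n_sd=0.5)
        assert out[1] == ["g"]


class TestEmbed2d:
    def test_planar_data_reconstructed_exactly(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=(40, 2)) * [5.0, 2.0]
        basis = np.linalg.qr(rng.normal(size=(6, 2)))[0]
        X = scores @ basis.T
        coords = embed_2d(X)
        # 2-D data: the two PCs capture everything
        recon_var = coords.var(axis=0).sum()
        z = (X - X.mean(0)) / X.std(0)
        assert recon_var == pytest.approx(z.var(axis=0).sum(), rel=1e-8)

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(50, 5)) @ np.diag([3, 2, 1, 0.5, 0.1])
        coords = embed_2d(X)
        Z = (X - X.mean(0)) / X.std(0)
        evals, evecs = np.linalg.eigh(np.cov(Z, rowvar=False, bias=False))
        order = np.argsort(evals)[::-1][:2]
        oracle = Z @ evecs[:, order]
        for j in range(2):
            v = evecs[:, order[j]]
            if v[np.argmax(np.abs(v))] < 0:
                oracle[:, j] = -oracle[:, j]
        assert np.allclose(coords, oracle, atol=1e-8)

    def test_constant_gene_dropped_with_warning(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 3))
        X[:, 1] = 7.0
        with pytest.warns(UserWarning):
            coords = embed_2d(X)
        assert coords.shape == (20, 2)

    def test_tsne_is_seeded(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(60, 4))
        a = embed_2d(X, method="tsne", random_state=5)
        b = embed_2d(X, method="tsne", random_state=5)
        assert np.array_equal(a, b)


class TestGridSurface:
    def test_constant_field_reproduced(self):
        rng = np.random.default_rng(5)
        coords = rng.random((80, 2))
        surf = landscape_surface(coords, np.full(80, 4.2), grid_n=30)
        assert surf.node_z_.shape == (30, 30)
        assert np.allclose(surf.node_z_, 4.2, atol=1e-8)

    def test_plane_is_penalty_free(self):
        rng = np.random.default_rng(6)
        coords = rng.random((400, 2))
        z = 3.0 * coords[:, 0] - 2.0 * coords[:, 1] + 1.0
        surf = landscape_surface(coords, z, grid_n=20, smoothness=1.0)
        xx, yy = np.meshgrid(surf.node_x_, surf.node_y_)
        truth = 3.0 * xx - 2.0 * yy + 1.0
        rmse = np.sqrt(((surf.node_z_ - truth) ** 2).mean())
        assert rmse < 1e-6

    def test_smooth_bump_recovered_below_noise_level(self):
        rng = np.random.default_rng(7)
        coords = rng.random((3000, 2))
        truth_fn = lambda x, y: 5.0 * np.exp(
            -((x - 0.5) ** 2 + (y - 0.5) ** 2) / 0.08)
        noise_sd = 1.0
        z = truth_fn(coords[:, 0], coords[:, 1]) \
            + rng.normal(0, noise_sd, 3000)
        surf = landscape_surface(coords, z, grid_n=30, smoothness=1.0)
        xx, yy = np.meshgrid(surf.node_x_, surf.node_y_)
        rmse = np.sqrt(((surf.node_z_ - truth_fn(xx, yy)) ** 2).mean())
        assert rmse < noise_sd

    def test_predict_interpolates_fit(self):
        rng = np.random.default_rng(8)
        coords = rng.random((500, 2))
        z = coords[:, 0] + coords[:, 1]
        surf = GridSurface(grid_n=15).fit(coords, z)
        pred = surf.predict(coords)
        assert np.allclose(pred, z, atol=1e-6)

    def test_collinear_points_rejected(self):
        coords = np.column_stack([np.arange(5.0), np.arange(5.0)])
        with pytest.raises(ValueError):
            GridSurface().fit(coords, np.arange(5.0))
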