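import numpy as np
import pytest
import scipy.stats

from burstscape import (
    ParamGrid,
    TelegraphParams,
    burst_frequency,
    burst_size,
    fit_mle_grid,
    gene_nll,
    sample_stationary,
    stationary_pmf,
)
from burstscape.telegraph import TruncationError

from .oracles import naive_grid_search, series_pmf, total_variation


class TestStationaryPmf:
    def test_no_transcription_is_point_mass_at_zero(self):
        pmf = stationary_pmf(TelegraphParams(1.0, 1.0, 0.0), m_max=5)
        assert np.allclose(pmf, [1, 0, 0, 0, 0, 0])

    def test_always_on_limit_is_poisson(self):
        pmf = stationary_pmf(TelegraphParams(50.0, 1e-6, 5.0), m_max=40)
        poisson = scipy.stats.poisson.pmf(np.arange(41), 5.0)
        assert np.abs(pmf - poisson).max() < 1e-4

    def test_matches_monte_carlo_sampler(self):
        params = TelegraphParams(0.5, 0.5, 20.0)
        pmf = stationary_pmf(params, m_max=100)
        draws = sample_stationary(params, 10**6, seed=7)
        emp = np.bincount(draws, minlength=101) / draws.size
        assert total_variation(pmf, emp) < 0.005

    @pytest.mark.parametrize(
        "theta_on,theta_off,theta_t",
        [(0.5, 0.5, 20.0), (2.0, 3.0, 30.0), (1.0, 1.0, 5.0),
         (0.2, 5.0, 10.0)],
    )
    def test_quadrature_matches_hypergeometric_series(
        self, theta_on, theta_off, theta_t
    ):
        pmf = stationary_pmf(
            TelegraphParams(theta_on, theta_off, theta_t), m_max=120)
        series = series_pmf(theta_on, theta_off, theta_t, 120)
        series /= series.sum()
        assert np.abs(pmf - series).max() < 1e-8

    def test_mean_matches_analytic(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            p = TelegraphParams(
                theta_on=float(rng.uniform(0.2, 5.0)),
                theta_off=float(rng.uniform(0.2, 5.0)),
                theta_t=float(rng.uniform(1.0, 30.0)),
            )
            pmf = stationary_pmf(p, m_max=200)
            assert pmf.min() >= 0
            assert pmf.sum() == pytest.approx(1.0, abs=1e-6)
            mean = (np.arange(201) * pmf).sum()
            assert mean == pytest.approx(p.mean, rel=1e-4)

    def test_truncation_error_when_mass_escapes(self):
        with pytest.raises(TruncationError):
            stationary_pmf(TelegraphParams(50.0, 0.01, 100.0), m_max=20)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            TelegraphParams(np.nan, 1.0, 1.0)
        with pytest.raises(ValueError):
            TelegraphParams(-1.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            TelegraphParams(1.0, 1.0, 1.0, theta_d=2.0)


class TestSampler:
    def test_zero_rate_gives_zeros(self):
        assert not sample_stationary(
            TelegraphParams(1.0, 1.0, 0.0), 100, seed=0).any()

    def test_sample_mean_near_analytic(self):
        params = TelegraphParams(1.0, 1.0, 20.0)
        draws = sample_stationary(params, 10**5, seed=3)
        se = draws.std() / np.sqrt(draws.size)
        assert abs(draws.mean() - 10.0) < 3 * se

    def test_identical_seed_identical_draws(self):
        params = TelegraphParams(0.7, 1.3, 15.0)
        a = sample_stationary(params, 1000, seed=9)
        b = sample_stationary(params, 1000, seed=9)
        assert np.array_equal(a, b)


class TestGeneNll:
    def test_certain_zero_has_zero_nll(self, small_grid):
        assert gene_nll(0, TelegraphParams(1.0, 1.0, 0.0), small_grid) == 0.0

    def test_mode_minimises_nll(self, small_grid):
        params = TelegraphParams(1.0, 1.0, 30.0)
        nlls = [gene_nll(c, params, small_grid)
                for c in range(small_grid.m_max + 1)]
        pmf = small_grid.pmf_for(params)
        assert np.argmin(nlls) == np.argmax(pmf)

    def test_equals_minus_log_pmf(self, small_grid):
        params = TelegraphParams(0.5, 0.5, 20.0)
        pmf = small_grid.pmf_for(params)
        for c in (0, 5, 17, 40):
            assert gene_nll(c, params, small_grid) == pytest.approx(
                -np.log(pmf[c]), abs=1e-8)

    def test_count_outside_support_raises(self, small_grid):
        with pytest.raises(ValueError):
            gene_nll(small_grid.m_max + 1, TelegraphParams(1, 1, 5),
                     small_grid)


class TestGridMle:
    def test_matches_naive_exhaustive_search(self, small_grid):
        rng = np.random.default_rng(5)
        for theta in [(1.0, 1.0, 30.0), (0.3, 2.0, 60.0), (3.0, 0.5, 10.0)]:
            counts = np.clip(
                sample_stationary(TelegraphParams(*theta), 200, seed=rng),
                0, small_grid.m_max)
            params, ll = fit_mle_grid(counts, small_grid)
            idx_oracle, ll_oracle = naive_grid_search(counts, small_grid)
            assert small_grid.index_of(params) == idx_oracle
            assert ll == pytest.approx(ll_oracle, abs=1e-9)

    def test_all_zero_counts_maximise_probability_of_zero(self, small_grid):
        params, _ = fit_mle_grid(np.zeros(50, dtype=int), small_grid)
        p0 = small_grid.pmf_for(params)[0]
        assert p0 >= small_grid.pmf[:, 0].max() - 1e-12

    def test_recovers_burst_size_within_one_grid_step(self, default_grid):
        grid = default_grid
        true = grid.params_at(grid.index_of(TelegraphParams(
            theta_on=float(grid.theta_on[10]),
            theta_off=float(grid.theta_off[10]),
            theta_t=float(grid.theta_t[15]))))
        counts = sample_stationary(true, 1000, seed=21)
        fitted, _ = fit_mle_grid(counts, grid)
        log_step = np.log(grid.theta_t[1] / grid.theta_t[0]) \
            + np.log(grid.theta_off[1] / grid.theta_off[0])
        ratio = abs(np.log(burst_size(fitted) / burst_size(true)))
        assert ratio <= log_step + 1e-9

    def test_empty_counts_raise(self, small_grid):
        with pytest.raises(ValueError):
            fit_mle_grid(np.array([], dtype=int), small_grid)


class TestBurstMetrics:
    def test_definitions(self):
        p = TelegraphParams(2.0, 10.0, 100.0)
        assert burst_size(p) == 10.0
        assert burst_frequency(p) == 2.0

    def test_scaling(self):
        p = TelegraphParams(2.0, 10.0, 100.0)
        doubled = TelegraphParams(2.0, 20.0, 100.0)
        assert burst_size(doubled) == burst_size(p) / 2
        assert burst_frequency(doubled) == burst_frequency(p)
        q = TelegraphParams(0.74, 1.0, 1.0)
        assert burst_frequency(q) == 0.74
        assert burst_size(q) == 1.0


class TestParamGrid:
    def test_cached_pmfs_are_normalised_distributions(self, small_grid):
        assert small_grid.pmf.min() >= 0
        sums = small_grid.pmf.sum(axis=1)
        assert np.abs(sums - 1.0).max() < 1e-6

    def test_axes_must_increase(self):
        with pytest.raises(ValueError):
            ParamGrid(np.array([1.0, 1.0]), np.array([1.0]),
                      np.array([1.0]), m_max=10)

    def test_index_round_trip(self, small_grid):
        for i in (0, 7, small_grid.n_points - 1):
            assert small_grid.index_of(small_grid.params_at(i)) == i
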