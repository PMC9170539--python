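import numpy as np
import pytest
from scipy import stats

from camsdm.grid import GridSpec, RasterLayer
from camsdm.indices import annual_totals, hellmann_eberle
from camsdm.occurrences import thin_per_cell
from camsdm.synthetic import (
    FieldParams,
    FlatResponse,
    GaussianResponse,
    LogisticResponse,
    SyntheticTruth,
    gen_monthly_precip,
    gen_smooth_fields,
    sample_presences,
    true_suitability,
)

from conftest import constant_layer, small_grid


class TestSmoothFields:
    def test_zero_sd_gives_constant_field(self, grid):
        params = FieldParams(grid=grid, means=(5.0,), sds=(0.0,), seed=0)
        stack = gen_smooth_fields(params, ["a"])
        assert np.allclose(stack["a"].values, 5.0)

    def test_seed_determinism(self, grid):
        params = FieldParams(grid=grid, means=(0.0, 1.0), sds=(1.0, 2.0), seed=3)
        a = gen_smooth_fields(params, ["x", "y"])
        b = gen_smooth_fields(params, ["x", "y"])
        for name in ("x", "y"):
            assert np.array_equal(a[name].values, b[name].values)

    def test_requested_cross_correlation(self):
        g = small_grid(100, 100)
        params = FieldParams(
            grid=g, means=(0.0, 0.0), sds=(1.0, 1.0),
            correlation_length=2.0, inter_field_correlation=0.9, seed=7,
        )
        stack = gen_smooth_fields(params, ["a", "b"])
        r = np.corrcoef(stack["a"].values.ravel(), stack["b"].values.ravel())[0, 1]
        assert 0.8 <= r <= 0.97

    def test_negative_pairwise_correlation_rejected(self, grid):
        with pytest.raises(ValueError):
            FieldParams(grid=grid, means=(0.0,), sds=(1.0,), inter_field_correlation=-0.5)


class TestMonthlyPrecip:
    def test_zero_variability_gives_quotient_one(self):
        g = small_grid(5, 5)
        series = gen_monthly_precip(g, n_years=10, mean_annual=600.0, interannual_log_sd=0.0, seed=0)
        q = hellmann_eberle(annual_totals(series))
        assert np.allclose(q.values, 1.0)

    def test_zero_mean_gives_all_zero(self):
        g = small_grid(3, 3)
        series = gen_monthly_precip(g, n_years=3, mean_annual=0.0, seed=0)
        assert np.all(series.values == 0.0)

    def test_58_year_high_variability_median_q_matches_oracle(self):
        g = small_grid(40, 40)
        series = gen_monthly_precip(g, n_years=58, mean_annual=500.0, interannual_log_sd=0.8, seed=5)
        q = hellmann_eberle(annual_totals(series))
        median_q = float(np.nanmedian(q.values))
        assert median_q > 5.0
        # direct simulation oracle: max/min ratio of 58 lognormal draws
        rng = np.random.default_rng(99)
        draws = np.exp(0.8 * rng.standard_normal((4000, 58)))
        oracle = np.median(draws.max(axis=1) / draws.min(axis=1))
        assert median_q == pytest.approx(oracle, rel=0.05)

    def test_seasonal_totals_preserved(self):
        g = small_grid(4, 4)
        series = gen_monthly_precip(g, n_years=3, mean_annual=480.0, interannual_log_sd=0.0, seasonality=0.8, seed=1)
        totals = series.values.sum(axis=1)
        assert np.allclose(totals, 480.0)
        assert np.all(series.values >= 0.0)

    def test_too_few_years_rejected(self):
        with pytest.raises(ValueError):
            gen_monthly_precip(small_grid(2, 2), n_years=1, mean_annual=100.0)


class TestTruth:
    def test_flat_truth_rejected(self):
        with pytest.raises(ValueError):
            SyntheticTruth(responses={"a": FlatResponse()})

    def test_logistic_midpoint_gives_half(self, grid):
        from camsdm.grid import RasterStack

        stack = RasterStack([constant_layer(grid, 3.0, "a")])
        truth = SyntheticTruth(responses={"a": LogisticResponse(midpoint=3.0, slope=2.0)})
        out = true_suitability(stack, truth)
        assert np.allclose(out.values, 0.5)

    def test_gaussian_center_gives_prevalence_scale(self, grid):
        from camsdm.grid import RasterStack

        stack = RasterStack([constant_layer(grid, 7.0, "a")])
        truth = SyntheticTruth(
            responses={"a": GaussianResponse(center=7.0, width=2.0)}, prevalence_scale=0.3
        )
        out = true_suitability(stack, truth)
        assert np.allclose(out.values, 0.3)

    def test_missing_predictor_errors(self, grid):
        from camsdm.grid import RasterStack

        stack = RasterStack([constant_layer(grid, 1.0, "a")])
        truth = SyntheticTruth(responses={"zzz": LogisticResponse(0.0, 1.0)})
        with pytest.raises(KeyError):
            true_suitability(stack, truth)


class TestPresenceSampling:
    def test_uniform_suitability_samples_uniformly(self):
        g = small_grid(10, 10)
        occ = sample_presences(constant_layer(g, 1.0, "s"), n_target=5000, seed=2)
        row, col = g.point_to_cell(occ.lon, occ.lat)
        counts = np.bincount(row * 10 + col, minlength=100)
        assert stats.chisquare(counts).pvalue > 0.01

    def test_zero_suitability_region_gets_no_records(self):
        g = small_grid(10, 10)
        vals = np.ones(g.shape)
        vals[5:, :] = 0.0  # south half unsuitable
        occ = sample_presences(RasterLayer(g, vals, "s"), n_target=500, seed=0)
        row, _ = g.point_to_cell(occ.lon, occ.lat)
        assert np.all(row < 5)

    def test_all_zero_weights_error(self):
        g = small_grid(3, 3)
        with pytest.raises(ValueError):
            sample_presences(constant_layer(g, 0.0, "s"), n_target=10)

    def test_exact_count_and_determinism(self):
        g = small_grid(5, 5)
        a = sample_presences(constant_layer(g, 1.0, "s"), n_target=77, seed=4)
        b = sample_presences(constant_layer(g, 1.0, "s"), n_target=77, seed=4)
        assert len(a) == 77
        assert a.table.equals(b.table)

    def test_biased_cluster_reduced_by_thinning(self):
        g = small_grid(10, 10)
        bias = np.full(g.shape, 1e-9)
        bias[0, 0] = 1.0  # observer effort piled on one cell
        occ = sample_presences(
            constant_layer(g, 1.0, "s"), n_target=200, bias=RasterLayer(g, bias, "bias"), seed=0
        )
        thinned = thin_per_cell(occ, cell_size=1.0, max_per_cell=5, seed=0)
        row, col = g.point_to_cell(thinned.lon, thinned.lat)
        in_cell = np.sum((row == 0) & (col == 0))
        assert in_cell <= 5
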