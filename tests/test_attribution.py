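import numpy as np
import pytest

from aridflux.attribution import (climate_attribution, coupling_vs_iav_curves,
                                  decompose_gpp_iav, gpp_et_coupling,
                                  partial_correlation)
from aridflux.budyko import classify_aridity
from aridflux.errors import ValidationError
from aridflux.grid import GriddedCube, GridField, GridSpec
from aridflux.variability import decompose_trend


def closed_form_partial(y, x, z):
    """rho_xy.z = (r_xy - r_xz r_yz) / sqrt((1-r_xz^2)(1-r_yz^2))."""
    r = np.corrcoef(np.vstack([y, x, z]))
    return (r[0, 1] - r[0, 2] * r[1, 2]) / np.sqrt((1 - r[0, 2] ** 2) * (1 - r[1, 2] ** 2))


class TestPartialCorrelation:
    def test_orthogonal_controls_reduce_to_pearson(self):
        rng = np.random.default_rng(0)
        n = 64
        x = rng.normal(size=n)
        y = 0.6 * x + rng.normal(size=n)
        # construct a control numerically orthogonal to both
        z = rng.normal(size=n)
        A = np.column_stack([np.ones(n), x, y])
        z -= A @ np.linalg.lstsq(A, z, rcond=None)[0]
        rho, _ = partial_correlation(y, x, z)
        plain = np.corrcoef(y, x)[0, 1]
        assert rho == pytest.approx(plain, abs=1e-10)

    def test_identical_series_give_one(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=20)
        z = rng.normal(size=20)
        rho, p = partial_correlation(x, x, z)
        assert rho == pytest.approx(1.0, abs=1e-12)
        assert p == 0.0

    def test_matches_three_variable_closed_form(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            y = rng.normal(size=12)
            x = 0.5 * y + rng.normal(size=12)
            z = 0.3 * y + rng.normal(size=12)
            rho, _ = partial_correlation(y, x, z)
            assert rho == pytest.approx(closed_form_partial(y, x, z), abs=1e-10)

    def test_symmetry_and_affine_invariance(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=15)
        x = rng.normal(size=15)
        z = rng.normal(size=15)
        r1, _ = partial_correlation(y, x, z)
        r2, _ = partial_correlation(x, y, z)
        assert r1 == pytest.approx(r2, abs=1e-12)
        r3, _ = partial_correlation(3.0 * y - 2.0, 0.5 * x + 7.0, 10.0 * z + 1.0)
        assert r3 == pytest.approx(r1, abs=1e-10)

    def test_constant_series_undefined(self):
        rho, p = partial_correlation(np.ones(10), np.arange(10.0), np.random.default_rng(0).normal(size=10))
        assert np.isnan(rho) and np.isnan(p)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            partial_correlation(np.ones(5), np.ones(6), np.ones(5))

    def test_two_controls_accepted(self):
        rng = np.random.default_rng(4)
        y = rng.normal(size=12)
        x = rng.normal(size=12)
        C = rng.normal(size=(2, 12))
        rho, p = partial_correlation(y, x, C)
        assert -1 <= rho <= 1 and 0 <= p <= 1

    def test_null_calibration_type_one_error(self):
        # alpha = 0.05 at N = 12 with 2 controls: rejection rate ~ 5%
        rng = np.random.default_rng(5)
        n_cells, rejections = 4000, 0
        for _ in range(n_cells):
            y = rng.normal(size=12)
            x = rng.normal(size=12)
            C = rng.normal(size=(2, 12))
            _, p = partial_correlation(y, x, C)
            rejections += p < 0.05
        assert rejections / n_cells == pytest.approx(0.05, abs=0.015)


def _grid(n):
    return GridSpec(np.array([0.0]), np.linspace(-179, 179, n))


class TestClimateAttribution:
    def test_water_limited_cells_flag_precipitation(self, world):
        att = climate_attribution(world.gpp_truth, world.p, world.t, world.sw)
        wl = world.water_limited & (world.ai_map.values > 0.05)
        frac_positive_sig = np.mean(att.significant["p"][wl]
                                    & (att.rho_p.values[wl] > 0))
        assert frac_positive_sig >= 0.9

    def test_humid_cells_prefer_radiation(self, world):
        humid = ~world.water_limited
        att = climate_attribution(world.gpp_truth, world.p, world.t, world.sw)
        assert np.nanmedian(att.rho_sw.values[humid]) > np.nanmedian(
            att.rho_p.values[humid])

    def test_null_gpp_significance_near_alpha(self):
        rng = np.random.default_rng(6)
        grid = GridSpec(np.linspace(-49.5, 49.5, 100), np.linspace(-178.2, 178.2, 100))
        years = np.arange(2000, 2012)
        shape = (12, 100, 100)
        cubes = [GriddedCube(grid, rng.normal(size=shape), years, units="x")
                 for _ in range(4)]
        att = climate_attribution(*cubes)
        rate = np.mean([att.significant[d].mean() for d in ("p", "t", "sw")])
        assert rate == pytest.approx(0.05, abs=0.01)


class TestCoupling:
    def test_exact_linear_coupling(self):
        grid = _grid(10)
        rng = np.random.default_rng(0)
        et = rng.normal(0, 10, (8, 1, 10))
        et -= et.mean(axis=0)
        gpp = 2.0 * et
        years = np.arange(2000, 2008)
        coup = gpp_et_coupling(GriddedCube(grid, gpp, years, units="g C m-2 yr-1"),
                               GriddedCube(grid, et, years, units="mm yr-1"))
        np.testing.assert_allclose(coup.beta_mean.values, 2.0, atol=1e-10)
        np.testing.assert_allclose(coup.r_mean.values, 1.0, atol=1e-10)

    def test_independent_series_beta_centered_on_zero(self):
        grid = _grid(500)
        rng = np.random.default_rng(1)
        years = np.arange(2000, 2012)
        gpp = GriddedCube(grid, rng.normal(size=(12, 1, 500)), years, units="g")
        et = GriddedCube(grid, rng.normal(size=(12, 1, 500)), years, units="mm")
        coup = gpp_et_coupling(gpp, et)
        assert abs(np.nanmean(coup.beta_mean.values)) < 0.05

    def test_beta_equals_r_times_sd_ratio(self, world):
        gpp_anom = decompose_trend(world.gpp_truth).anomalies
        et_anom = decompose_trend(world.et).anomalies
        coup = gpp_et_coupling(gpp_anom, et_anom)
        sd_g = gpp_anom.values.std(axis=0)
        sd_e = et_anom.values.std(axis=0)
        expected = coup.r_mean.values * sd_g / sd_e
        np.testing.assert_allclose(coup.beta_mean.values, expected, atol=1e-10)

    def test_multiple_products_averaged(self):
        grid = _grid(20)
        rng = np.random.default_rng(2)
        years = np.arange(2000, 2010)
        et = rng.normal(0, 5, (10, 1, 20))
        et -= et.mean(axis=0)
        gpp = GriddedCube(grid, 1.5 * et, years, units="g C m-2 yr-1")
        products = {f"p{k}": GriddedCube(grid, et, years, units="mm yr-1")
                    for k in range(3)}
        coup = gpp_et_coupling(gpp, products)
        assert len(coup.beta_per_product) == 3
        np.testing.assert_allclose(coup.beta_mean.values, 1.5, atol=1e-10)


class TestIAVDecomposition:
    def test_noise_free_coupled_cell_ratio_one(self):
        grid = _grid(5)
        rng = np.random.default_rng(3)
        et = rng.normal(0, 10, (10, 1, 5))
        et -= et.mean(axis=0)
        gpp = 3.0 * et
        years = np.arange(2000, 2010)
        coup = gpp_et_coupling(GriddedCube(grid, gpp, years, units="g"),
                               GriddedCube(grid, et, years, units="mm"))
        _, ratio = decompose_gpp_iav(coup.beta_mean, coup.sigma_et_mean,
                                     coup.sigma_gpp)
        np.testing.assert_allclose(ratio.values, 1.0, atol=1e-10)

    def test_ratio_below_one_with_independent_noise(self):
        # GPP = beta ET + noise: predicted^2 + noise var = actual variance
        grid = _grid(200)
        rng = np.random.default_rng(4)
        years = np.arange(2000, 2012)
        et = rng.normal(0, 10, (12, 1, 200))
        et -= et.mean(axis=0)
        noise = rng.normal(0, 15, (12, 1, 200))
        noise -= noise.mean(axis=0)
        gpp = 2.0 * et + noise
        coup = gpp_et_coupling(GriddedCube(grid, gpp, years, units="g"),
                               GriddedCube(grid, et, years, units="mm"))
        _, ratio = decompose_gpp_iav(coup.beta_mean, coup.sigma_et_mean,
                                     coup.sigma_gpp)
        assert np.all(ratio.values <= 1.0 + 1e-9)
        assert np.all(ratio.values > 0)
        # variance additivity with the fitted slope: residual var fills the gap
        resid = gpp - coup.beta_mean.values * et
        pred = coup.beta_mean.values * et.std(axis=0)
        total = pred**2 + resid.std(axis=0) ** 2
        np.testing.assert_allclose(total, gpp.std(axis=0) ** 2, rtol=1e-8)

    def test_decoupled_humid_cells_have_low_ratio(self, world):
        gpp_anom = decompose_trend(world.gpp_truth).anomalies
        et_anom = decompose_trend(world.et).anomalies
        coup = gpp_et_coupling(gpp_anom, et_anom)
        _, ratio = decompose_gpp_iav(coup.beta_mean, coup.sigma_et_mean,
                                     coup.sigma_gpp)
        humid = ~world.water_limited
        wl = world.water_limited
        assert np.nanmedian(ratio.values[humid]) < np.nanmedian(ratio.values[wl])


class TestCurves:
    def test_constant_coefficient_map_flat(self, world):
        const = GridField(world.grid, np.full(world.grid.shape, 0.4), units="1")
        sigma = GridField(world.grid, np.abs(world.gpp_truth.values.std(axis=0)),
                          units="g C m-2 yr-1")
        curves = coupling_vs_iav_curves({"c": const}, sigma)
        c = curves["c"]
        np.testing.assert_allclose(c.mean[c.count > 0], 0.4, atol=1e-12)

    def test_bins_partition_unmasked_cells(self, world):
        sigma = GridField(world.grid, world.gpp_truth.values.std(axis=0),
                          units="g C m-2 yr-1")
        curves = coupling_vs_iav_curves({"ai": world.ai_map}, sigma)
        assert curves["ai"].count.sum() == world.grid.nlat * world.grid.nlon

    def test_r_et_rises_with_gpp_iav(self, world):
        from scipy.stats import spearmanr

        gpp_anom = decompose_trend(world.gpp_truth).anomalies
        et_anom = decompose_trend(world.et).anomalies
        coup = gpp_et_coupling(gpp_anom, et_anom)
        curves = coupling_vs_iav_curves({"r_et": coup.r_mean}, coup.sigma_gpp)
        c = curves["r_et"]
        means = c.mean[np.isfinite(c.mean)]
        upper = means[means.size // 2:]
        rho = spearmanr(np.arange(upper.size), upper).statistic
        assert rho > 0
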