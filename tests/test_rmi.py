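import numpy as np
import pytest

from lexcast.data_io import MortalitySurface, subset_surface
from lexcast.errors import AlignmentError, DomainError, InsufficientDataError
from lexcast.rmi import RMIConfig, blend_weight, fit_rmi, forecast_rmi
from lexcast.synthetic import generate_scenario, preset


def linear_trend_surface(alpha, beta, n_years=30, first_year=1970, m0=0.01):
    """Surface whose improvement rates are exactly alpha + beta*(t - t_mid)."""
    n_ages = len(alpha)
    years = first_year + np.arange(n_years)
    t_mid = years[1:].mean()
    u = years[1:] - t_mid
    rho = alpha[:, None] + np.outer(beta, u)
    rates = np.empty((n_ages, n_years))
    rates[:, 0] = m0
    for j in range(1, n_years):
        rates[:, j] = rates[:, j - 1] * (1.0 - rho[:, j - 1] / 100.0)
    surface = MortalitySurface(
        population_code="LIN", sex="total", ages=np.arange(n_ages),
        years=years, rates=rates,
    )
    return surface, rho, u


class TestFit:
    def test_construct_and_recover_penalty_zero(self):
        x = np.arange(40)
        alpha = 1.0 + 1.5 * np.exp(-(((x - 20) / 12.0) ** 2))
        beta = 0.02 * (x - 20) / 20
        surface, _, _ = linear_trend_surface(alpha, beta)
        cfg = RMIConfig(penalty_weight=0.0, presmooth=False, n_draws=10, seed=0)
        fit = fit_rmi(surface, config=cfg)
        np.testing.assert_allclose(fit.alpha, alpha, atol=1e-8)
        np.testing.assert_allclose(fit.beta, beta, atol=1e-8)
        np.testing.assert_allclose(fit.sigma, 0.0, atol=1e-8)

    def test_wmax_zero_reference_independent(self):
        scen = generate_scenario(preset("stagnation-recovery", seed=3))
        base = subset_surface(scen.target, year_range=(1965, 1990))
        refs = [subset_surface(r, year_range=(1965, 1990)) for r in scen.references]
        cfg = RMIConfig(w_max=0.0, n_draws=30, seed=5)
        with_refs = fit_rmi(base, references=refs, config=cfg)
        without = fit_rmi(base, references=[], config=cfg)
        np.testing.assert_array_equal(with_refs.alpha, without.alpha)
        np.testing.assert_array_equal(with_refs.beta, without.beta)
        np.testing.assert_array_equal(with_refs.sigma, without.sigma)
        np.testing.assert_array_equal(
            with_refs.parameter_draws, without.parameter_draws
        )
        assert with_refs.has_reference and not without.has_reference
        fc_with = forecast_rmi(with_refs, horizon=5, n_draws=50, seed=1)
        fc_without = forecast_rmi(without, horizon=5, n_draws=50, seed=1)
        np.testing.assert_array_equal(
            fc_with.rate_quantiles, fc_without.rate_quantiles
        )

    def test_huge_penalty_age_linear_oracle(self):
        rng = np.random.default_rng(4)
        x = np.arange(30)
        alpha = 1.0 + 0.03 * x + 0.4 * rng.standard_normal(30)
        beta = -0.01 + 0.001 * x + 0.01 * rng.standard_normal(30)
        surface, rho, u = linear_trend_surface(alpha, beta)
        # independent oracle: per-age OLS profiles, then OLS line over age
        alpha_ols = rho.mean(axis=1)
        beta_ols = rho @ u / (u @ u)
        design = np.column_stack([np.ones(30), x])
        alpha_line = design @ np.linalg.lstsq(design, alpha_ols, rcond=None)[0]
        beta_line = design @ np.linalg.lstsq(design, beta_ols, rcond=None)[0]
        # the ridge remainder is O(1/penalty): ~1e-4 at 1e8, <1e-6 at 1e11
        fit = fit_rmi(
            surface,
            config=RMIConfig(penalty_weight=1e8, presmooth=False, n_draws=5, seed=0),
        )
        np.testing.assert_allclose(fit.alpha, alpha_line, atol=1e-4)
        np.testing.assert_allclose(fit.beta, beta_line, atol=1e-4)
        fit = fit_rmi(
            surface,
            config=RMIConfig(penalty_weight=1e11, presmooth=False, n_draws=5, seed=0),
        )
        np.testing.assert_allclose(fit.alpha, alpha_line, atol=1e-6)
        np.testing.assert_allclose(fit.beta, beta_line, atol=1e-6)

    def test_draw_means_near_point_estimates(self):
        scen = generate_scenario(preset("regular", seed=11, exposure=1e6))
        fit = fit_rmi(scen.target, config=RMIConfig(seed=2, n_draws=200))
        assert fit.parameter_draws.shape == (200, 2, scen.target.n_ages)
        se_a = fit.parameter_draws[:, 0].std(axis=0) / np.sqrt(200)
        se_b = fit.parameter_draws[:, 1].std(axis=0) / np.sqrt(200)
        frac_a = np.mean(
            np.abs(fit.parameter_draws[:, 0].mean(axis=0) - fit.alpha)
            <= 3 * np.maximum(se_a, 1e-12)
        )
        frac_b = np.mean(
            np.abs(fit.parameter_draws[:, 1].mean(axis=0) - fit.beta)
            <= 3 * np.maximum(se_b, 1e-12)
        )
        assert frac_a > 0.9 and frac_b > 0.9

    def test_sigma_nonnegative(self):
        scen = generate_scenario(preset("regular", seed=1))
        fit = fit_rmi(scen.target, config=RMIConfig(seed=0, n_draws=20))
        assert np.all(fit.sigma >= 0)

    def test_short_base_period(self):
        x = np.arange(10)
        surface, _, _ = linear_trend_surface(np.full(10, 1.0), np.zeros(10), n_years=8)
        with pytest.raises(InsufficientDataError):
            fit_rmi(surface)

    def test_reference_grid_mismatch(self):
        surface, _, _ = linear_trend_surface(np.full(10, 1.0), np.zeros(10))
        other, _, _ = linear_trend_surface(np.full(10, 1.0), np.zeros(10), n_years=20)
        with pytest.raises(AlignmentError):
            fit_rmi(surface, references=[other])

    def test_parameter_recovery_poisson(self):
        """RMSE(beta_hat - beta_true) small over interior ages."""
        scen = generate_scenario(preset("regular", seed=7, exposure=1e6))
        u = scen.truth.years[1:] - scen.truth.years[1:].mean()
        beta_true = scen.truth.rho @ u / (u @ u)
        fit = fit_rmi(scen.target, config=RMIConfig(seed=1))
        interior = slice(5, 106)
        rmse = np.sqrt(np.mean((fit.beta - beta_true)[interior] ** 2))
        assert rmse <= 0.2


class TestBlendWeight:
    def test_monotone_in_h(self):
        w = blend_weight(np.arange(1, 40), w_max=0.5, tau=10.0)
        assert np.all(np.diff(w) > 0)
        assert w[-1] < 0.5

    def test_tau_zero_jumps_to_wmax(self):
        assert blend_weight(1, w_max=0.7, tau=0.0) == 0.7
        assert blend_weight(25, w_max=0.7, tau=0.0) == 0.7


class TestForecast:
    def test_geometric_cumulation_exact(self):
        c = 1.5
        surface, _, _ = linear_trend_surface(np.full(15, c), np.zeros(15))
        cfg = RMIConfig(penalty_weight=0.0, presmooth=False, n_draws=1, seed=0)
        fit = fit_rmi(surface, config=cfg)
        result = forecast_rmi(fit, horizon=6, n_draws=1, seed=0)
        i = result.levels.index(0.5)
        for h in range(1, 7):
            expected = surface.rates[:, -1] * (1 - c / 100.0) ** h
            np.testing.assert_allclose(
                result.rate_quantiles[i, :, h - 1], expected, rtol=1e-10
            )

    def test_blend_limit_equals_reference_trend(self):
        c_tgt, c_ref = 0.5, 2.5
        target, _, _ = linear_trend_surface(np.full(15, c_tgt), np.zeros(15))
        ref_s, _, _ = linear_trend_surface(np.full(15, c_ref), np.zeros(15))
        cfg = RMIConfig(
            w_max=1.0, tau=0.0, penalty_weight=0.0, presmooth=False,
            n_draws=1, seed=0,
        )
        fit = fit_rmi(target, references=[ref_s], config=cfg)
        result = forecast_rmi(fit, horizon=5, n_draws=1, seed=0)
        i = result.levels.index(0.5)
        for h in range(1, 6):
            expected = target.rates[:, -1] * (1 - c_ref / 100.0) ** h
            np.testing.assert_allclose(
                result.rate_quantiles[i, :, h - 1], expected, rtol=1e-9
            )

    def test_quantile_monotonicity(self):
        scen = generate_scenario(preset("regular", seed=2))
        fit = fit_rmi(scen.target, config=RMIConfig(seed=0, n_draws=100))
        result = forecast_rmi(fit, horizon=10, n_draws=500, seed=1)
        q = result.e0_quantiles.to_numpy()
        assert np.all(np.diff(q, axis=0) >= 0)

    def test_jumpoff_continuity_without_noise(self):
        surface, _, _ = linear_trend_surface(np.zeros(12), np.zeros(12))
        cfg = RMIConfig(penalty_weight=0.0, presmooth=False, n_draws=1, seed=0)
        fit = fit_rmi(surface, config=cfg)
        result = forecast_rmi(fit, horizon=1, n_draws=1, seed=0)
        i = result.levels.index(0.5)
        np.testing.assert_allclose(
            result.rate_quantiles[i, :, 0], fit.jumpoff_rates, rtol=1e-12
        )

    def test_dynamic_age_shift(self):
        """Forecast improvement peak sits older than base-period mean peak."""
        scen = generate_scenario(preset("regular", seed=20, exposure=1e6))
        fit = fit_rmi(scen.target, config=RMIConfig(seed=0))
        fc = forecast_rmi(
            fit, horizon=20, n_draws=200, seed=1, include_residual_noise=False
        )
        med = fc.median_rates()
        rho_h20 = 100.0 * (1.0 - med[:, 19] / med[:, 18])
        base_peak = scen.truth.ages[np.argmax(scen.truth.rho.mean(axis=1))]
        forecast_peak = scen.truth.ages[np.argmax(rho_h20)]
        assert forecast_peak > base_peak

    def test_trend_change_capture_with_reference(self):
        """Recovering reference raises the h=15 median e0 vs w_max=0."""
        scen = generate_scenario(preset("stagnation-recovery", seed=42))
        base = subset_surface(scen.target, year_range=(1965, 1990))
        refs = [subset_surface(r, year_range=(1965, 1990)) for r in scen.references]
        blended = fit_rmi(base, references=refs, config=RMIConfig(w_max=0.5, seed=3))
        domestic = fit_rmi(base, references=refs, config=RMIConfig(w_max=0.0, seed=3))
        e_blend = forecast_rmi(blended, horizon=15, n_draws=300, seed=4)
        e_dom = forecast_rmi(domestic, horizon=15, n_draws=300, seed=4)
        assert e_blend.median_e0().iloc[-1] > e_dom.median_e0().iloc[-1]

    def test_clamp_saturation_warns(self):
        surface, _, _ = linear_trend_surface(np.full(12, 1.0), np.full(12, 0.5))
        cfg = RMIConfig(penalty_weight=0.0, presmooth=False, n_draws=1, seed=0)
        fit = fit_rmi(surface, config=cfg)
        with pytest.warns(RuntimeWarning, match="clamp"):
            forecast_rmi(fit, horizon=40, n_draws=5, seed=0)

    def test_domain_errors(self):
        surface, _, _ = linear_trend_surface(np.zeros(12), np.zeros(12))
        fit = fit_rmi(surface, config=RMIConfig(n_draws=5, seed=0, presmooth=False))
        with pytest.raises(DomainError):
            forecast_rmi(fit, horizon=0, n_draws=5)
        with pytest.raises(DomainError):
            forecast_rmi(fit, horizon=5, n_draws=0)
        with pytest.raises(DomainError):
            forecast_rmi(fit, jumpoff=np.ones(3), horizon=5, n_draws=5)

    def test_seed_reproducibility(self):
        scen = generate_scenario(preset("regular", seed=9))
        fit = fit_rmi(scen.target, config=RMIConfig(seed=1, n_draws=50))
        r1 = forecast_rmi(fit, horizon=5, n_draws=100, seed=6)
        r2 = forecast_rmi(fit, horizon=5, n_draws=100, seed=6)
        np.testing.assert_array_equal(r1.rate_quantiles, r2.rate_quantiles)
        np.testing.assert_array_equal(
            r1.e0_quantiles.to_numpy(), r2.e0_quantiles.to_numpy()
        )
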