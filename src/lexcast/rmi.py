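"""Probabilistic forecasting of rates of mortality improvement.

The model works in improvement-rate space rather than log-rate space.
For each age x the (optionally pre-smoothed) improvement surface is
described by a linear time trend

    rho(x, t) = alpha_x + beta_x * (t - t_mid) + eps_x(t),

with alpha and beta coupled across ages by an order-2 difference
(smoothness) penalty. Because beta_x varies with age, the age profile
of improvements can shift over time — the dynamic age shift that a
fixed-loading log-bilinear model cannot represent. A pooled fit on
reference populations provides a second trend which is blended in with
a weight that grows with forecast horizon,

    w(h) = w_max * (1 - exp(-h / tau)),

so the forecast can leave a stagnating domestic trend and approach the
reference trend — the mechanism for capturing anticipated catching-up.
Estimation uncertainty comes from a residual bootstrap over years;
forecast rates are cumulated multiplicatively from the jump-off column
and summarized as quantiles of rates and e0.

This is a documented reconstruction of a model whose exact equations
are not public; every constant lives in :class:`RMIConfig` and is
echoed into outputs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data_io import MortalitySurface, check_aligned
from .errors import AlignmentError, DomainError, InsufficientDataError
from .improvement import improvement_rates, smooth_surface, _difference_penalty
from .results import DEFAULT_LEVELS, ForecastResult

logger = logging.getLogger(__name__)

MIN_BASE_YEARS = 10


@dataclass(frozen=True)
class RMIConfig:
    """Tuning constants of the improvement-rate forecaster.

    w_max
        Asymptotic weight of the reference trend (0 disables blending).
    tau
        Horizon scale (years) of the blending weight; tau -> 0 makes
        the weight jump to w_max from the first forecast year.
    clamp
        Symmetric bound (percent) on forecast improvement rates.
    penalty_weight
        Order-2 smoothness penalty on alpha and beta over age.
    n_draws
        Bootstrap draws of (alpha, beta) stored in the fit.
    presmooth
        Pre-smooth the rate surface (Poisson P-splines when counts are
        present, log-Gaussian otherwise) before differentiating.
    """

    w_max: float = 0.5
    tau: float = 10.0
    clamp: float = 25.0
    penalty_weight: float = 10.0
    n_draws: int = 200
    #: pre-smoothing of the rate surface before differentiation is
    #: optional: the precision-weighted, age-penalized trend fit already
    #: pools information across ages, and keeping the trend fit on the
    #: raw surface lets the residual bootstrap replicate the estimator
    #: exactly (which is what makes the intervals calibrated)
    presmooth: bool = False
    smooth_lambda_age: float = 50.0
    smooth_lambda_year: float = 100.0
    seed: int | None = None


@dataclass
class RMIFit:
    """Per-age improvement level alpha (percent), time trend beta
    (percent/year), residual sd sigma, the analogous pooled reference
    profiles (when references were supplied), bootstrap parameter
    draws, and an echo of the configuration."""

    population_code: str
    sex: str
    ages: np.ndarray
    base_years: np.ndarray
    t_mid: float
    alpha: np.ndarray
    beta: np.ndarray
    sigma: np.ndarray
    parameter_draws: np.ndarray  # (n_draws, 2, n_ages): [:,0]=alpha, [:,1]=beta
    config: RMIConfig
    reference_alpha: np.ndarray | None = None
    reference_beta: np.ndarray | None = None
    jumpoff_rates: np.ndarray | None = None
    open_interval: bool = True

    @property
    def has_reference(self) -> bool:
        return self.reference_alpha is not None


def _penalized_trend_fit(
    rho: np.ndarray,
    u: np.ndarray,
    penalty_weight: float,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit alpha_x + beta_x * u_t to rho (n_ages x n_years).

    u must be centered (sum zero), which decouples the alpha and beta
    ridge problems; both share an order-2 difference penalty over age.
    ``weights`` are per-age precisions (normalized to mean 1): ages with
    little information are pulled toward their neighbours by the
    penalty instead of exporting noise into the extrapolated trend.
    """
    n_ages, n_years = rho.shape
    pen = penalty_weight * _difference_penalty(n_ages, 2)
    s_uu = float(np.sum(u**2))
    alpha_ols = rho.mean(axis=1)
    beta_ols = rho @ u / s_uu
    if penalty_weight == 0:
        return alpha_ols, beta_ols
    if weights is None:
        w = np.ones(n_ages)
    else:
        w = np.asarray(weights, dtype=float)
        w = w / w.mean()
    alpha = np.linalg.solve(
        n_years * np.diag(w) + pen, n_years * w * alpha_ols
    )
    beta = np.linalg.solve(s_uu * np.diag(w) + pen, s_uu * w * beta_ols)
    return alpha, beta


def _precision_weights(s: MortalitySurface) -> np.ndarray | None:
    """Per-age precision of observed improvement rates, or None.

    The Poisson variance of rho(x, t) is ~ 100^2 (1/D(x,t) + 1/D(x,t-1));
    its inverse (averaged over years) weights the trend fit.
    """
    if s.deaths is None:
        return None
    d = np.maximum(s.deaths, 0.5)
    pois_var = np.mean(100.0**2 * (1.0 / d[:, 1:] + 1.0 / d[:, :-1]), axis=1)
    return 1.0 / pois_var


def _model_view(s: MortalitySurface, config: RMIConfig) -> tuple[np.ndarray, np.ndarray]:
    """(improvement matrix, rate surface) as the model sees them.

    With presmoothing the model works from the denoised surface — its
    improvement rates drive the trend fit and its last column is the
    jump-off, so measurement noise in the final observed year does not
    bias the launch level.
    """
    if config.presmooth:
        rates = smooth_surface(
            s.deaths,
            s.exposures,
            lambda_age=config.smooth_lambda_age,
            lambda_year=config.smooth_lambda_year,
            rates=s.rates,
        )
        s = MortalitySurface(
            population_code=s.population_code,
            sex=s.sex,
            ages=s.ages,
            years=s.years,
            rates=rates,
            open_interval=s.open_interval,
        )
    return improvement_rates(s).rho, s.rates


def fit_rmi(
    target: MortalitySurface,
    references: list[MortalitySurface] | None = None,
    config: RMIConfig = RMIConfig(),
) -> RMIFit:
    """Fit the penalized age-trend model, plus a pooled reference trend.

    References must share the target's age/year grid; they are pooled
    with equal weights in improvement space. With ``config.w_max == 0``
    references are ignored entirely and the fit is identical to a
    reference-free fit (apart from the ``reference_*`` fields).
    """
    references = references or []
    if target.n_years < MIN_BASE_YEARS:
        raise InsufficientDataError(
            f"base period must span >= {MIN_BASE_YEARS} years, got {target.n_years}"
        )
    for r in references:
        if not (
            np.array_equal(r.ages, target.ages)
            and np.array_equal(r.years, target.years)
        ):
            raise AlignmentError(
                f"reference {r.population_code!r} grid differs from target"
            )

    rho, model_rates = _model_view(target, config)
    rho_raw = improvement_rates(target).rho if config.presmooth else rho
    rho_years = target.years[1:].astype(float)
    t_mid = float(rho_years.mean())
    u = rho_years - t_mid
    weights = _precision_weights(target)
    alpha, beta = _penalized_trend_fit(rho, u, config.penalty_weight, weights)
    fitted = alpha[:, None] + np.outer(beta, u)
    # estimation uncertainty is judged against the *raw* surface:
    # smoothing must not hide the sampling noise from the bootstrap
    resid = rho_raw - fitted
    n_years = rho.shape[1]
    raw_var = np.sum(resid**2, axis=1) / max(n_years - 2, 1)
    # predictive sigma targets the *process* dispersion of future
    # improvements; when counts are available the (known) Poisson
    # measurement variance of rho is subtracted from the raw residual
    # variance so measurement noise is not propagated into future rates
    if target.deaths is not None:
        d = np.maximum(target.deaths, 0.5)
        pois_var = np.mean(
            100.0**2 * (1.0 / d[:, 1:] + 1.0 / d[:, :-1]), axis=1
        )
        sigma = np.sqrt(np.clip(raw_var - pois_var, 0.0, None))
    else:
        sigma = np.sqrt(raw_var)

    rng = np.random.default_rng(config.seed)
    n_draws = max(int(config.n_draws), 1)
    draws = np.empty((n_draws, 2, target.n_ages))
    for d in range(n_draws):
        cols = rng.integers(0, n_years, size=n_years)
        rho_star = fitted + resid[:, cols]
        a_d, b_d = _penalized_trend_fit(rho_star, u, config.penalty_weight, weights)
        draws[d, 0], draws[d, 1] = a_d, b_d

    ref_alpha = ref_beta = None
    if references:
        pooled = np.mean(
            [_model_view(r, config)[0] for r in references], axis=0
        )
        ref_weights = None
        if all(r.deaths is not None for r in references):
            ref_weights = np.mean([_precision_weights(r) for r in references], axis=0)
        ref_alpha, ref_beta = _penalized_trend_fit(
            pooled, u, config.penalty_weight, ref_weights
        )

    return RMIFit(
        population_code=target.population_code,
        sex=target.sex,
        ages=target.ages.copy(),
        base_years=target.years.copy(),
        t_mid=t_mid,
        alpha=alpha,
        beta=beta,
        sigma=sigma,
        parameter_draws=draws,
        config=config,
        reference_alpha=ref_alpha,
        reference_beta=ref_beta,
        jumpoff_rates=target.jumpoff_rates(),
        open_interval=target.open_interval,
    )


def blend_weight(h: np.ndarray | int, w_max: float, tau: float) -> np.ndarray:
    """Reference weight at forecast step h >= 1."""
    h = np.asarray(h, dtype=float)
    if tau <= 1e-12:
        return np.where(h >= 1, w_max, 0.0)
    return w_max * (1.0 - np.exp(-h / tau))


def forecast_rmi(
    fit: RMIFit,
    jumpoff: np.ndarray | None = None,
    horizon: int = 10,
    n_draws: int = 1000,
    seed: int | None = None,
    levels: tuple[float, ...] = DEFAULT_LEVELS,
    include_residual_noise: bool = True,
) -> ForecastResult:
    """Simulate forecast improvement paths and cumulate them into rates.

    Per draw and step h: the target trend alpha + beta*(T+h - t_mid) is
    blended with the reference trend under w(h), per-age Gaussian
    residual noise (sd sigma) is added, the result is clamped to
    +/- config.clamp percent, and rates are cumulated from the jump-off
    column: ``m(x,T+h) = m(x,T) * prod_{j<=h} (1 - rho_hat(x,j)/100)``.
    """
    if horizon < 1 or n_draws < 1:
        raise DomainError("horizon and n_draws must be >= 1")
    if fit.parameter_draws.shape[0] < 1:
        raise DomainError("fit carries no parameter draws")
    jumpoff = np.asarray(
        fit.jumpoff_rates if jumpoff is None else jumpoff, dtype=float
    )
    if jumpoff.shape != (len(fit.ages),):
        raise DomainError("jumpoff must be one rate per age")
    cfg = fit.config
    rng = np.random.default_rng(seed)
    T = float(fit.base_years[-1])
    h = np.arange(1, horizon + 1, dtype=float)
    t_fore = T + h - fit.t_mid  # (horizon,)
    w = blend_weight(h, cfg.w_max if fit.has_reference else 0.0, cfg.tau)

    idx = rng.integers(0, fit.parameter_draws.shape[0], size=n_draws)
    alpha_d = fit.parameter_draws[idx, 0]  # (n_draws, n_ages)
    beta_d = fit.parameter_draws[idx, 1]

    g_tgt = alpha_d[:, :, None] + beta_d[:, :, None] * t_fore[None, None, :]
    if fit.has_reference:
        g_ref = (
            fit.reference_alpha[:, None] + np.outer(fit.reference_beta, t_fore)
        )[None, :, :]
    else:
        g_ref = 0.0
    rho_hat = (1.0 - w)[None, None, :] * g_tgt + w[None, None, :] * g_ref
    if include_residual_noise:
        rho_hat = rho_hat + fit.sigma[None, :, None] * rng.standard_normal(
            rho_hat.shape
        )
    n_cells = rho_hat.size
    clamped = np.abs(rho_hat) > cfg.clamp
    if clamped.sum() > 0.05 * n_cells:
        msg = (
            f"improvement clamp saturated in {clamped.sum() / n_cells:.1%} of cells"
        )
        logger.warning(msg)
        warnings.warn(msg, RuntimeWarning, stacklevel=2)
    rho_hat = np.clip(rho_hat, -cfg.clamp, cfg.clamp)

    factors = 1.0 - rho_hat / 100.0
    rates = jumpoff[None, :, None] * np.cumprod(factors, axis=2)
    years = int(fit.base_years[-1]) + 1 + np.arange(horizon)
    return ForecastResult.from_rate_draws(
        population_code=fit.population_code,
        sex=fit.sex,
        ages=fit.ages,
        years=years,
        rate_draws=rates,
        seed=seed,
        levels=levels,
        open_interval=fit.open_interval,
    )
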