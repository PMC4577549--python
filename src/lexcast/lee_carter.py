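"""The classic log-bilinear mortality model.

``log m(x,t) = a(x) + b(x) k(t)`` with the usual identification
constraints (sum of b equal to 1, sum of k equal to 0), fit by the first
singular pair of the centered log-rate matrix, and ``k`` extrapolated as
a random walk with drift. Forecast rates are launched from the observed
jump-off rates rather than the fitted ``a(x)``, which removes jump-off
bias. The forecast age pattern of change is ``b(x)`` forever — the
model's defining rigidity, asserted in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import MortalitySurface
from .errors import DegenerateFitError, DomainError, InsufficientDataError
from .results import DEFAULT_LEVELS, ForecastResult


@dataclass
class LCFit:
    """Fitted parameters: a (age means), b (age loadings, sum 1),
    k (period index, sum 0), random-walk drift and innovation sd,
    drift standard error, and the jump-off rate column."""

    population_code: str
    sex: str
    ages: np.ndarray
    years: np.ndarray
    a: np.ndarray
    b: np.ndarray
    k: np.ndarray
    drift: float
    sigma_rw: float
    sigma_drift: float
    jumpoff_rates: np.ndarray
    open_interval: bool = True

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """(age table of a, b; year table of k) for CSV export."""
        age_tab = pd.DataFrame({"age": self.ages, "a": self.a, "b": self.b})
        year_tab = pd.DataFrame({"year": self.years, "k": self.k})
        return age_tab, year_tab


def fit_lc(s: MortalitySurface) -> LCFit:
    """Fit by SVD of the centered log-rate matrix.

    Sign convention: k is oriented so its drift is <= 0 (declining
    mortality moves k downward). Raises DegenerateFitError on a
    constant surface (rank-0 centered matrix).
    """
    if s.n_years < 3:
        raise InsufficientDataError("need >= 3 years to fit")
    log_m = s.log_rates()
    a = log_m.mean(axis=1)
    centered = log_m - a[:, None]
    u, sv, vt = np.linalg.svd(centered, full_matrices=False)
    if sv[0] <= 1e-12 * max(centered.shape):
        raise DegenerateFitError("centered log-rate matrix has rank 0")
    b = u[:, 0]
    k = sv[0] * vt[0]
    scale = b.sum()
    if abs(scale) < 1e-12:
        raise DegenerateFitError("age loadings sum to ~0; cannot normalize")
    b = b / scale
    k = k * scale
    # columns of centered sum to zero over years, hence sum(k) == 0 already
    k = k - k.mean()
    # note: the constraint sum(b) = 1 fixes the sign of the pair; with
    # positive loadings, declining mortality yields drift <= 0
    n = s.n_years
    drift = (k[-1] - k[0]) / (n - 1)
    resid = np.diff(k) - drift
    sigma_rw = float(np.sqrt(np.sum(resid**2) / max(len(resid) - 1, 1)))
    sigma_drift = sigma_rw / np.sqrt(n - 1)
    return LCFit(
        population_code=s.population_code,
        sex=s.sex,
        ages=s.ages.copy(),
        years=s.years.copy(),
        a=a,
        b=b,
        k=k,
        drift=float(drift),
        sigma_rw=sigma_rw,
        sigma_drift=float(sigma_drift),
        jumpoff_rates=s.jumpoff_rates(),
        open_interval=s.open_interval,
    )


def simulate_k_paths(
    fit: LCFit,
    horizon: int,
    n_draws: int,
    rng: np.random.Generator,
    include_drift_uncertainty: bool = True,
) -> np.ndarray:
    """(n_draws, horizon) random-walk-with-drift continuations of k."""
    drift = np.full(n_draws, fit.drift)
    if include_drift_uncertainty:
        drift = drift + fit.sigma_drift * rng.standard_normal(n_draws)
    innov = fit.sigma_rw * rng.standard_normal((n_draws, horizon))
    steps = drift[:, None] + innov
    return fit.k[-1] + np.cumsum(steps, axis=1)


def forecast_lc(
    fit: LCFit,
    horizon: int,
    n_draws: int = 1000,
    seed: int | None = None,
    include_drift_uncertainty: bool = True,
    levels: tuple[float, ...] = DEFAULT_LEVELS,
) -> ForecastResult:
    """Simulate future rates and summarize them as quantiles.

    Rates are reconstructed from the jump-off column as
    ``m(x, T+h) = m(x, T) * exp(b(x) * (k_path(h) - k(T)))``.
    """
    if horizon < 1 or n_draws < 1:
        raise DomainError("horizon and n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    k_paths = simulate_k_paths(fit, horizon, n_draws, rng, include_drift_uncertainty)
    delta = k_paths - fit.k[-1]  # (n_draws, horizon)
    log_jump = np.log(fit.jumpoff_rates)
    log_rates = log_jump[None, :, None] + fit.b[None, :, None] * delta[:, None, :]
    years = fit.years[-1] + 1 + np.arange(horizon)
    return ForecastResult.from_rate_draws(
        population_code=fit.population_code,
        sex=fit.sex,
        ages=fit.ages,
        years=years,
        rate_draws=np.exp(log_rates),
        seed=seed,
        levels=levels,
        open_interval=fit.open_interval,
    )
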