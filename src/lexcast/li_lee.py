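"""Coherent multi-population extension of the log-bilinear model.

A common factor ``B(x) K(t)`` is fit to the (weighted) mean log-rate
surface of the group; each population keeps a residual factor
``b_i(x) k_i(t)`` whose period index is modeled as a mean-reverting
AR(1) (coefficient clamped below 1), so that forecast log-rate gaps
between populations stay bounded instead of diverging.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import MortalitySurface, check_aligned
from .errors import DomainError
from .lee_carter import LCFit, fit_lc, simulate_k_paths
from .results import DEFAULT_LEVELS, ForecastResult

PHI_MAX = 0.98

#: residual factors with singular value below this fraction of the
#: common factor's are treated as exactly zero (identical populations)
_RESIDUAL_TOL = 1e-10


@dataclass
class CoherentFit:
    """Common factor (B, K with its random-walk parameters) plus, per
    population, age means a_i, residual factor (b_i, k_i), AR(1)
    coefficient phi_i, innovation sd sigma_i, and jump-off rates."""

    populations: list[str]
    sex: str
    ages: np.ndarray
    years: np.ndarray
    B: np.ndarray
    K: np.ndarray
    K_drift: float
    K_sigma: float
    K_sigma_drift: float
    a: dict[str, np.ndarray]
    b: dict[str, np.ndarray]
    k: dict[str, np.ndarray]
    phi: dict[str, float]
    sigma: dict[str, float]
    jumpoff_rates: dict[str, np.ndarray]
    weights: np.ndarray
    open_interval: bool = True

    def common_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        return (
            pd.DataFrame({"age": self.ages, "B": self.B}),
            pd.DataFrame({"year": self.years, "K": self.K}),
        )


def _first_singular_pair(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    u, sv, vt = np.linalg.svd(mat, full_matrices=False)
    return u[:, 0], sv[0] * vt[0], sv[0]


def fit_li_lee(
    surfaces: list[MortalitySurface],
    weights: np.ndarray | None = None,
) -> CoherentFit:
    """Fit the coherent model to >= 2 aligned surfaces.

    The group surface is the weighted mean of the per-population log
    rates (equal weights by default); its first singular pair gives the
    common factor under the usual constraints. Residual surfaces give
    the population factors; phi_i is the least-squares AR(1)
    coefficient of k_i, clamped to [0, 0.98].
    """
    if len(surfaces) < 2:
        raise DomainError("need >= 2 populations for a coherent fit")
    check_aligned(surfaces)
    if weights is None:
        weights = np.full(len(surfaces), 1.0 / len(surfaces))
    else:
        weights = np.asarray(weights, dtype=float)
        if len(weights) != len(surfaces) or np.any(weights < 0) or weights.sum() == 0:
            raise DomainError("weights must be nonnegative and sum > 0")
        weights = weights / weights.sum()

    log_mats = [s.log_rates() for s in surfaces]
    group_log = sum(w * lm for w, lm in zip(weights, log_mats))
    ref = surfaces[0]
    group_surface = MortalitySurface(
        population_code="GROUP",
        sex=ref.sex,
        ages=ref.ages.copy(),
        years=ref.years.copy(),
        rates=np.exp(group_log),
        open_interval=ref.open_interval,
    )
    common: LCFit = fit_lc(group_surface)
    B, K = common.b, common.k

    a, b, k, phi, sigma, jumpoff = {}, {}, {}, {}, {}, {}
    for s, log_m in zip(surfaces, log_mats):
        code = s.population_code
        a_i = log_m.mean(axis=1)
        resid = log_m - a_i[:, None] - np.outer(B, K)
        u_i, k_i, sv_i = _first_singular_pair(resid)
        if sv_i <= _RESIDUAL_TOL * max(resid.shape) * max(np.abs(K).max(), 1.0):
            b_i = np.full(s.n_ages, 1.0 / s.n_ages)
            k_i = np.zeros(s.n_years)
            phi_i, sigma_i = 0.0, 0.0
        else:
            scale = u_i.sum()
            if abs(scale) < 1e-12:
                b_i = np.full(s.n_ages, 1.0 / s.n_ages)
                k_i = np.zeros(s.n_years)
                phi_i, sigma_i = 0.0, 0.0
            else:
                b_i = u_i / scale
                k_i = k_i * scale
                k_i = k_i - k_i.mean()  # rows of resid sum to 0, so already ~0
                denom = np.sum(k_i[:-1] ** 2)
                phi_i = float(np.sum(k_i[:-1] * k_i[1:]) / denom) if denom > 0 else 0.0
                phi_i = float(np.clip(phi_i, 0.0, PHI_MAX))
                eps = k_i[1:] - phi_i * k_i[:-1]
                sigma_i = float(np.sqrt(np.sum(eps**2) / max(len(eps) - 1, 1)))
        a[code], b[code], k[code] = a_i, b_i, k_i
        phi[code], sigma[code] = phi_i, sigma_i
        jumpoff[code] = s.jumpoff_rates()

    return CoherentFit(
        populations=[s.population_code for s in surfaces],
        sex=ref.sex,
        ages=ref.ages.copy(),
        years=ref.years.copy(),
        B=B,
        K=K,
        K_drift=common.drift,
        K_sigma=common.sigma_rw,
        K_sigma_drift=common.sigma_drift,
        a=a,
        b=b,
        k=k,
        phi=phi,
        sigma=sigma,
        jumpoff_rates=jumpoff,
        weights=weights,
        open_interval=ref.open_interval,
    )


def forecast_li_lee(
    fit: CoherentFit,
    horizon: int,
    n_draws: int = 1000,
    seed: int | None = None,
    include_drift_uncertainty: bool = True,
    levels: tuple[float, ...] = DEFAULT_LEVELS,
) -> dict[str, ForecastResult]:
    """Joint forecast: one shared K path set, independent AR(1) k_i.

    Per population, ``m_i(x,T+h) = m_i(x,T) * exp(B dK + b_i dk_i)``.
    Returns a ForecastResult per population code.
    """
    if horizon < 1 or n_draws < 1:
        raise DomainError("horizon and n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    common_proxy = LCFit(
        population_code="GROUP",
        sex=fit.sex,
        ages=fit.ages,
        years=fit.years,
        a=np.zeros(len(fit.ages)),
        b=fit.B,
        k=fit.K,
        drift=fit.K_drift,
        sigma_rw=fit.K_sigma,
        sigma_drift=fit.K_sigma_drift,
        jumpoff_rates=np.ones(len(fit.ages)),
        open_interval=fit.open_interval,
    )
    K_paths = simulate_k_paths(
        common_proxy, horizon, n_draws, rng, include_drift_uncertainty
    )
    dK = K_paths - fit.K[-1]  # (n_draws, horizon)
    years = fit.years[-1] + 1 + np.arange(horizon)

    out: dict[str, ForecastResult] = {}
    for code in fit.populations:
        phi_i, sigma_i = fit.phi[code], fit.sigma[code]
        k_paths = np.empty((n_draws, horizon))
        prev = np.full(n_draws, fit.k[code][-1])
        for h in range(horizon):
            prev = phi_i * prev + sigma_i * rng.standard_normal(n_draws)
            k_paths[:, h] = prev
        dk = k_paths - fit.k[code][-1]
        log_jump = np.log(fit.jumpoff_rates[code])
        log_rates = (
            log_jump[None, :, None]
            + fit.B[None, :, None] * dK[:, None, :]
            + fit.b[code][None, :, None] * dk[:, None, :]
        )
        out[code] = ForecastResult.from_rate_draws(
            population_code=code,
            sex=fit.sex,
            ages=fit.ages,
            years=years,
            rate_draws=np.exp(log_rates),
            seed=seed,
            levels=levels,
            open_interval=fit.open_interval,
        )
    return out
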