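"""Rates of mortality improvement on Lexis surfaces.

The improvement rate is the percent annual decline of the death rate,

    rho(x, t) = 100 * (1 - m(x, t) / m(x, t - 1)),

so positive values mean improving survival. Values are classified into
four bands (strong > 4 %, moderate in (0.5, 4], stagnating in
[-0.5, 0.5], deteriorating < -0.5) for Lexis heat maps, and raw
surfaces can be smoothed with a two-dimensional penalized B-spline fit
before differentiation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.linalg import solve

from .data_io import MortalitySurface
from .errors import DegenerateDataError, DomainError, InsufficientDataError

BANDS = ("strong", "moderate", "stagnating", "deteriorating")

#: band thresholds in percent per year
STRONG_ABOVE = 4.0
STAGNATION_HALF_WIDTH = 0.5


@dataclass
class ImprovementSurface:
    """Age x year grid of improvement rates in percent per year.

    The year axis is one shorter than the parent surface (the first
    data year has no predecessor).
    """

    ages: np.ndarray
    years: np.ndarray
    rho: np.ndarray
    band: np.ndarray | None = None

    def classify(self) -> "ImprovementSurface":
        """Attach the categorical band matrix (in place) and return self."""
        self.band = classify_bands(self.rho)
        return self

    def to_frame(self) -> pd.DataFrame:
        """Long table (year, age, rho[, band])."""
        ages, years = np.meshgrid(self.ages, self.years, indexing="ij")
        df = pd.DataFrame(
            {"year": years.ravel(), "age": ages.ravel(), "rho": self.rho.ravel()}
        )
        if self.band is not None:
            df["band"] = self.band.ravel()
        return df


def improvement_rates(s: MortalitySurface) -> ImprovementSurface:
    """Improvement-rate surface of a mortality surface.

    Requires at least two years of data; the result's year axis is
    ``s.years[1:]``.
    """
    if s.n_years < 2:
        raise InsufficientDataError("need >= 2 years to compute improvement rates")
    rho = 100.0 * (1.0 - s.rates[:, 1:] / s.rates[:, :-1])
    return ImprovementSurface(ages=s.ages.copy(), years=s.years[1:].copy(), rho=rho)


def rho_to_log_ratio(rho: np.ndarray) -> np.ndarray:
    """Alternative derivative convention: -100 * dlog m for a given rho."""
    return -100.0 * np.log1p(-np.asarray(rho) / 100.0)


def classify_bands(rho):
    """Band label(s) for improvement rate(s) in percent.

    strong if rho > 4; moderate if 0.5 < rho <= 4; stagnating if
    -0.5 <= rho <= 0.5; deteriorating if rho < -0.5. Ties at the
    stagnation edges go to stagnating; the tie at 4 goes to moderate.
    """
    arr = np.asarray(rho, dtype=float)
    if np.any(~np.isfinite(arr)):
        raise DomainError("improvement rate must be finite")
    out = np.where(
        arr > STRONG_ABOVE,
        "strong",
        np.where(
            arr > STAGNATION_HALF_WIDTH,
            "moderate",
            np.where(arr >= -STAGNATION_HALF_WIDTH, "stagnating", "deteriorating"),
        ),
    )
    if np.isscalar(rho) or arr.ndim == 0:
        return str(out)
    return out


# ---------------------------------------------------------------------
# 2-d P-spline smoothing
# ---------------------------------------------------------------------

def _bspline_basis(grid: np.ndarray, knot_spacing: float, degree: int = 3) -> np.ndarray:
    """Equally-spaced cubic B-spline design matrix over a 1-d grid."""
    lo, hi = float(grid[0]), float(grid[-1])
    n_seg = max(int(np.ceil((hi - lo) / knot_spacing)), 1)
    step = (hi - lo) / n_seg
    # fully uniform knots (outer padding at the same step) so that the
    # difference-penalty null space is exactly the polynomial space
    knots = lo + step * np.arange(-degree, n_seg + degree + 1)
    n_basis = len(knots) - degree - 1
    design = np.empty((len(grid), n_basis))
    for j in range(n_basis):
        coef = np.zeros(n_basis)
        coef[j] = 1.0
        design[:, j] = BSpline(knots, coef, degree, extrapolate=False)(grid)
    design[np.isnan(design)] = 0.0
    return design

def _difference_penalty(n_basis: int, order: int = 2) -> np.ndarray:
    d = np.diff(np.eye(n_basis), n=order, axis=0)
    return d.T @ d


def smooth_surface(
    deaths: np.ndarray | None,
    exposures: np.ndarray | None,
    lambda_age: float = 100.0,
    lambda_year: float = 100.0,
    *,
    rates: np.ndarray | None = None,
    knot_spacing: float = 5.0,
    penalty_order: int = 2,
    max_iter: int = 50,
    tol: float = 1e-8,
    template: MortalitySurface | None = None,
) -> np.ndarray | MortalitySurface:
    """Smooth a mortality surface with 2-d penalized B-splines.

    With ``deaths`` and ``exposures``, a Poisson likelihood with
    log-exposure offset is maximized by penalized IRLS (knots every
    ``knot_spacing`` ages/years, order-``penalty_order`` difference
    penalties on the tensor-product coefficients). When counts are
    absent a Gaussian fit on log raw ``rates`` is used instead.

    Returns a positive rate matrix of the input shape, or a new
    :class:`MortalitySurface` when ``template`` is given.
    """
    for name, lam in (("lambda_age", lambda_age), ("lambda_year", lambda_year)):
        if not np.isfinite(lam) or lam < 0:
            raise DomainError(f"{name} must be finite and >= 0")
    if template is not None and rates is None and deaths is None:
        rates = template.rates
        if template.deaths is not None and template.exposures is not None:
            deaths, exposures = template.deaths, template.exposures

    poisson = deaths is not None and exposures is not None
    if poisson:
        deaths = np.asarray(deaths, dtype=float)
        exposures = np.asarray(exposures, dtype=float)
        if deaths.shape != exposures.shape:
            raise DomainError("deaths and exposures shapes differ")
        if np.any(deaths < 0):
            raise DomainError("deaths must be >= 0")
        if np.any(exposures <= 0):
            raise DomainError("exposures must be > 0")
        if np.any(np.all(deaths == 0, axis=0)) or np.any(np.all(deaths == 0, axis=1)):
            raise DegenerateDataError("a whole age row or year column has zero deaths")
        shape = deaths.shape
        raw = np.log(np.maximum(deaths, 0.5) / exposures)
    else:
        if rates is None:
            raise DomainError("need either deaths+exposures or rates")
        rates = np.asarray(rates, dtype=float)
        if np.any(rates <= 0):
            raise DomainError("rates must be > 0 for log-Gaussian smoothing")
        shape = rates.shape
        raw = np.log(rates)

    n_age, n_year = shape
    ba = _bspline_basis(np.arange(n_age, dtype=float), knot_spacing)
    by = _bspline_basis(np.arange(n_year, dtype=float), knot_spacing)
    ka, ky = ba.shape[1], by.shape[1]
    pa = np.kron(_difference_penalty(ka, penalty_order), np.eye(ky))
    py = np.kron(np.eye(ka), _difference_penalty(ky, penalty_order))
    pen = lambda_age * pa + lambda_year * py
    basis = np.kron(ba, by)  # rows ordered age-major, matching raw.ravel()

    # Gaussian start (also the full answer in the no-counts case)
    theta = solve(
        basis.T @ basis + pen + 1e-10 * np.eye(ka * ky),
        basis.T @ raw.ravel(),
        assume_a="pos",
    )
    if poisson:
        y = deaths.ravel()
        log_exp = np.log(exposures).ravel()
        for _ in range(max_iter):
            eta = basis @ theta
            mu = np.exp(log_exp + eta)
            z = eta + (y - mu) / mu
            bw = basis * mu[:, None]
            theta_new = solve(
                bw.T @ basis + pen + 1e-10 * np.eye(ka * ky),
                bw.T @ z,
                assume_a="pos",
            )
            step = np.max(np.abs(theta_new - theta))
            theta = theta_new
            if step < tol:
                break
    smoothed = np.exp(basis @ theta).reshape(shape)
    if template is not None:
        return MortalitySurface(
            population_code=template.population_code,
            sex=template.sex,
            ages=template.ages.copy(),
            years=template.years.copy(),
            rates=smoothed,
            open_interval=template.open_interval,
        )
    return smoothed
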