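"""Period life tables and life expectancy at birth.

The closure conventions are deliberately simple and deterministic:
``q = m / (1 + (1 - a) m)`` for closed intervals, and the open interval
is closed with ``q = 1``, ``L = l / m``, ``e = 1 / m``. Defaults
``a_interior = 0.5`` and ``a0 = 0.1`` are configurable; with ``a = 0.5``
everywhere a constant hazard ``mu`` yields ``e0 = 1/mu`` exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import MortalitySurface
from .errors import DomainError

DEFAULT_A0 = 0.1
DEFAULT_A_INTERIOR = 0.5


@dataclass(frozen=True)
class LifeTable:
    """Single-year period life table (radix 1.0).

    Columns: age ``x``; central death rate ``m``; fraction of interval
    lived by decedents ``a``; death probability ``q``; survivors ``l``;
    deaths ``d``; person-years in interval ``L``; person-years above x
    ``T``; remaining life expectancy ``e``.
    """

    x: np.ndarray
    m: np.ndarray
    a: np.ndarray
    q: np.ndarray
    l: np.ndarray
    d: np.ndarray
    L: np.ndarray
    T: np.ndarray
    e: np.ndarray

    @property
    def e0(self) -> float:
        """Life expectancy at birth."""
        return float(self.e[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {c: getattr(self, c) for c in ("x", "m", "a", "q", "l", "d", "L", "T", "e")}
        )


def build_life_table(
    m: np.ndarray,
    a0: float = DEFAULT_A0,
    a_interior: float = DEFAULT_A_INTERIOR,
    open_interval: bool = True,
    ages: np.ndarray | None = None,
) -> LifeTable:
    """Build a period life table from a vector of central death rates.

    Parameters
    ----------
    m
        Central death rates per single-year age interval, all > 0.
    a0, a_interior
        Average fraction of the interval lived by those dying in it, for
        age 0 and all other closed intervals.
    open_interval
        If true, the last age is an open interval closed with
        ``q = 1``, ``L = l/m``, ``e = 1/m``.
    """
    m = np.asarray(m, dtype=float)
    if m.ndim != 1 or len(m) == 0:
        raise DomainError("m must be a nonempty 1-d vector")
    if np.any(~np.isfinite(m)):
        raise DomainError("NaN or infinite death rate in input")
    if np.any(m <= 0):
        raise DomainError("all death rates must be > 0")
    for name, val in (("a0", a0), ("a_interior", a_interior)):
        if not 0 < val < 1:
            raise DomainError(f"{name} must lie in (0, 1), got {val}")
    n = len(m)
    a = np.full(n, a_interior)
    a[0] = a0

    q = m / (1.0 + (1.0 - a) * m)
    if open_interval:
        q[-1] = 1.0
    l = np.empty(n)
    l[0] = 1.0
    if n > 1:
        np.cumprod(1.0 - q[:-1], out=l[1:])
    d = l * q
    L = np.empty(n)
    if n > 1:
        L[:-1] = l[1:] + a[:-1] * d[:-1]
    if open_interval:
        L[-1] = l[-1] / m[-1]
    else:
        L[-1] = l[-1] - (1.0 - a[-1]) * d[-1]
    T = np.cumsum(L[::-1])[::-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(l > 0, T / l, 0.0)
    x = np.arange(n) if ages is None else np.asarray(ages, dtype=int)
    return LifeTable(x=x, m=m, a=a, q=q, l=l, d=d, L=L, T=T, e=e)


def e0_from_rates(
    m: np.ndarray,
    a0: float = DEFAULT_A0,
    a_interior: float = DEFAULT_A_INTERIOR,
    open_interval: bool = True,
    axis: int = -1,
) -> np.ndarray:
    """Vectorized life expectancy at birth.

    ``m`` may have any number of leading dimensions (draws, years, ...)
    with ages along ``axis``; a scalar e0 is returned per age schedule.
    Used in forecast simulation where millions of small life tables
    would be too slow one at a time.
    """
    m = np.moveaxis(np.asarray(m, dtype=float), axis, -1)
    if np.any(~np.isfinite(m)) or np.any(m <= 0):
        raise DomainError("all death rates must be finite and > 0")
    n = m.shape[-1]
    a = np.full(n, a_interior)
    a[0] = a0
    q = m / (1.0 + (1.0 - a) * m)
    if open_interval:
        q[..., -1] = 1.0
    l = np.ones_like(m)
    np.cumprod(1.0 - q[..., :-1], axis=-1, out=l[..., 1:])
    d = l * q
    L = np.empty_like(m)
    L[..., :-1] = l[..., 1:] + a[:-1] * d[..., :-1]
    if open_interval:
        L[..., -1] = l[..., -1] / m[..., -1]
    else:
        L[..., -1] = l[..., -1] - (1.0 - a[-1]) * d[..., -1]
    return L.sum(axis=-1)


def e0_series(
    s: MortalitySurface,
    a0: float = DEFAULT_A0,
    a_interior: float = DEFAULT_A_INTERIOR,
) -> pd.Series:
    """Per-year life expectancy at birth of a mortality surface."""
    out = np.empty(s.n_years)
    for j, year in enumerate(s.years):
        try:
            out[j] = build_life_table(
                s.rates[:, j], a0=a0, a_interior=a_interior,
                open_interval=s.open_interval,
            ).e0
        except DomainError as exc:
            raise DomainError(f"year {year}: {exc}") from exc
    return pd.Series(out, index=pd.Index(s.years, name="year"), name="e0")
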