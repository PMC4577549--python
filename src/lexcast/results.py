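"""Shared containers for probabilistic forecasts."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError
from .lifetable import DEFAULT_A0, DEFAULT_A_INTERIOR, e0_from_rates

#: quantile levels reported by every forecaster: the median plus the
#: bounds of the 50, 67, 80 and 95 % prediction intervals
DEFAULT_LEVELS = (0.025, 0.10, 0.165, 0.25, 0.5, 0.75, 0.835, 0.90, 0.975)


@dataclass
class ForecastResult:
    """Quantile summary of simulated future death rates and e0.

    ``rate_quantiles`` has shape (n_levels, n_ages, n_years);
    ``e0_quantiles`` is a levels x years table in years of life
    expectancy at birth. Raw e0 draws are retained for calibration
    studies.
    """

    population_code: str
    sex: str
    ages: np.ndarray
    years: np.ndarray
    levels: tuple[float, ...]
    rate_quantiles: np.ndarray
    e0_quantiles: pd.DataFrame
    n_draws: int
    seed: int | None = None
    e0_draws: np.ndarray | None = None

    @classmethod
    def from_rate_draws(
        cls,
        population_code: str,
        sex: str,
        ages: np.ndarray,
        years: np.ndarray,
        rate_draws: np.ndarray,
        seed: int | None = None,
        levels: tuple[float, ...] = DEFAULT_LEVELS,
        a0: float = DEFAULT_A0,
        a_interior: float = DEFAULT_A_INTERIOR,
        open_interval: bool = True,
    ) -> "ForecastResult":
        """Summarize an (n_draws, n_ages, n_years) array of rate draws."""
        rate_draws = np.asarray(rate_draws, dtype=float)
        if rate_draws.ndim != 3:
            raise DomainError("rate_draws must be (n_draws, n_ages, n_years)")
        levels = tuple(sorted(levels))
        # e0 per draw per year: move ages last
        e0 = e0_from_rates(
            np.moveaxis(rate_draws, 1, -1),
            a0=a0,
            a_interior=a_interior,
            open_interval=open_interval,
        )  # (n_draws, n_years)
        rate_q = np.quantile(rate_draws, levels, axis=0)
        e0_q = pd.DataFrame(
            np.quantile(e0, levels, axis=0),
            index=pd.Index(levels, name="quantile"),
            columns=pd.Index(np.asarray(years, dtype=int), name="year"),
        )
        return cls(
            population_code=population_code,
            sex=sex,
            ages=np.asarray(ages, dtype=int),
            years=np.asarray(years, dtype=int),
            levels=levels,
            rate_quantiles=rate_q,
            e0_quantiles=e0_q,
            n_draws=rate_draws.shape[0],
            seed=seed,
            e0_draws=e0,
        )

    def median_e0(self) -> pd.Series:
        s = self.e0_quantiles.loc[0.5].copy()
        s.name = "e0"
        return s

    def median_rates(self) -> np.ndarray:
        i = self.levels.index(0.5)
        return self.rate_quantiles[i]

    def e0_long_frame(self) -> pd.DataFrame:
        """Long CSV form: population, sex, quantile, year, e0."""
        df = self.e0_quantiles.stack().rename("e0").reset_index()
        df.insert(0, "sex", self.sex)
        df.insert(0, "population", self.population_code)
        return df
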