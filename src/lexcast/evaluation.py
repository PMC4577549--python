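"""Retrospective forecast evaluation.

Fit each model on a base period, forecast a held-out horizon, and score
the predictive *median* e0 against observed e0 with per-year forecast
errors (forecast minus observed, so overestimation is positive) and
their mean absolute error. A model raising a typed lexcast error is
recorded as an ``error:<Type>`` status row without aborting the run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import lee_carter, li_lee, rmi
from .data_io import MortalitySurface, subset_surface
from .errors import AlignmentError, DomainError, LexcastError
from .lifetable import e0_series
from .results import ForecastResult

ModelFn = Callable[..., ForecastResult]


def forecast_errors(forecast_e0: pd.Series, observed_e0: pd.Series) -> pd.Series:
    """Per-year forecast error, forecast minus observed (years)."""
    if not forecast_e0.index.equals(observed_e0.index):
        raise AlignmentError(
            f"year grids differ: {list(forecast_e0.index)} vs {list(observed_e0.index)}"
        )
    out = forecast_e0 - observed_e0
    out.name = "fe"
    return out


def mae(errors) -> float:
    """Mean of absolute forecast errors (years)."""
    arr = np.asarray(errors, dtype=float)
    if arr.size == 0:
        raise DomainError("cannot average an empty error series")
    return float(np.mean(np.abs(arr)))


@dataclass
class EvalRow:
    population: str
    sex: str
    model: str
    status: str  # "ok" or "error:<Type>"
    years: np.ndarray | None = None
    fe: pd.Series | None = None
    mae: float | None = None


@dataclass
class EvaluationReport:
    base: tuple[int, int]
    horizon_end: int
    rows: list[EvalRow] = field(default_factory=list)
    model_configs: dict = field(default_factory=dict)

    def row(self, model: str) -> EvalRow:
        for r in self.rows:
            if r.model == model:
                return r
        raise KeyError(model)

    def fe_frame(self) -> pd.DataFrame:
        """Long per-year forecast-error table."""
        parts = []
        for r in self.rows:
            if r.fe is None:
                continue
            df = r.fe.rename("fe").reset_index()
            df.insert(0, "model", r.model)
            df.insert(0, "sex", r.sex)
            df.insert(0, "population", r.population)
            parts.append(df)
        if not parts:
            return pd.DataFrame(columns=["population", "sex", "model", "year", "fe"])
        return pd.concat(parts, ignore_index=True)

    def mae_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "population": r.population,
                    "sex": r.sex,
                    "model": r.model,
                    "status": r.status,
                    "mae": r.mae,
                }
                for r in self.rows
            ]
        )

    def summary_text(self) -> str:
        lines = [
            f"retrospective evaluation: base {self.base[0]}-{self.base[1]}, "
            f"horizon through {self.horizon_end}"
        ]
        for r in self.rows:
            if r.status == "ok":
                lines.append(
                    f"  {r.population} {r.sex} {r.model:12s} MAE = {r.mae:.3f} years"
                )
            else:
                lines.append(f"  {r.population} {r.sex} {r.model:12s} {r.status}")
        return "\n".join(lines)


# ---------------------------------------------------------------------
# model registry
# ---------------------------------------------------------------------

def _run_lee_carter(base, refs, horizon, n_draws, seed, **opts) -> ForecastResult:
    fit = lee_carter.fit_lc(base)
    return lee_carter.forecast_lc(fit, horizon=horizon, n_draws=n_draws, seed=seed)


def _run_li_lee(base, refs, horizon, n_draws, seed, **opts) -> ForecastResult:
    if not refs:
        raise DomainError("coherent model needs at least one reference population")
    fit = li_lee.fit_li_lee([base] + list(refs))
    results = li_lee.forecast_li_lee(fit, horizon=horizon, n_draws=n_draws, seed=seed)
    return results[base.population_code]

def _run_rmi(base, refs, horizon, n_draws, seed, **opts) -> ForecastResult:
    config = opts.get("config", rmi.RMIConfig())
    fit = rmi.fit_rmi(base, references=list(refs), config=config)
    return rmi.forecast_rmi(fit, horizon=horizon, n_draws=n_draws, seed=seed)


MODEL_REGISTRY: dict[str, ModelFn] = {
    "lee_carter": _run_lee_carter,
    "li_lee": _run_li_lee,
    "rmi": _run_rmi,
}


def run_retrospective(
    observed: MortalitySurface,
    references: Mapping[str, Sequence[MortalitySurface]] | None = None,
    base: tuple[int, int] = (1965, 1990),
    horizon_end: int = 2009,
    models: Sequence[str | ModelFn] = ("lee_carter", "rmi"),
    n_draws: int = 500,
    seed: int | None = None,
    model_options: Mapping[str, dict] | None = None,
) -> EvaluationReport:
    """Fit on ``base``, forecast through ``horizon_end``, score vs observed.

    ``references`` maps model name to the reference surfaces that model
    should see (full-span surfaces; they are subset to the base period
    here). Model failures of :class:`LexcastError` type become
    ``error:<Type>`` rows.
    """
    references = references or {}
    model_options = model_options or {}
    if horizon_end <= base[1]:
        raise DomainError("horizon_end must lie after the base period")
    if horizon_end > observed.years[-1]:
        raise DomainError(
            f"horizon end {horizon_end} beyond observed data "
            f"({observed.years[-1]}); cannot score"
        )
    base_surface = subset_surface(observed, year_range=base)
    horizon = horizon_end - base[1]
    fore_years = np.arange(base[1] + 1, horizon_end + 1)
    observed_e0 = e0_series(observed).loc[fore_years[0]: fore_years[-1]]

    report = EvaluationReport(
        base=base,
        horizon_end=horizon_end,
        model_configs={
            "n_draws": n_draws,
            "seed": seed,
            **{k: repr(v) for k, v in model_options.items()},
        },
    )
    for model in models:
        if callable(model):
            name = getattr(model, "__name__", "custom")
            fn = model
        else:
            name = model
            try:
                fn = MODEL_REGISTRY[name]
            except KeyError:
                raise DomainError(f"unknown model name {name!r}") from None
        refs = [
            subset_surface(r, year_range=base) for r in references.get(name, [])
        ]
        try:
            result = fn(
                base_surface,
                refs,
                horizon=horizon,
                n_draws=n_draws,
                seed=seed,
                **model_options.get(name, {}),
            )
            fe = forecast_errors(result.median_e0(), observed_e0)
            report.rows.append(
                EvalRow(
                    population=observed.population_code,
                    sex=observed.sex,
                    model=name,
                    status="ok",
                    years=fore_years,
                    fe=fe,
                    mae=mae(fe),
                )
            )
        except LexcastError as exc:
            report.rows.append(
                EvalRow(
                    population=observed.population_code,
                    sex=observed.sex,
                    model=name,
                    status=f"error:{type(exc).__name__}",
                )
            )
    return report
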