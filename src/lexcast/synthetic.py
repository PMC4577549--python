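"""Synthetic mortality surfaces with known latent structure.

Surfaces are built in improvement-rate space: a Gompertz-Makeham
baseline age schedule is propagated forward by a configurable
improvement field (a Gaussian-in-age bump whose peak age drifts
linearly over time), modified by additive regime shocks (stagnation,
crisis, recovery) on rectangular Lexis windows. Observed deaths are
Poisson given per-age exposures; reference populations replay the
target's latent improvement field with a lead (lag) and attenuation,
emulating countries that are ahead on the same trajectory.

Because the field is specified in improvement space and cumulated, the
estimand of the improvement-rate forecaster is known exactly, which is
what makes recovery and calibration experiments possible offline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .data_io import MortalitySurface
from .errors import ConfigError, DomainError
from .lifetable import e0_from_rates

MIN_DEATHS = 0.5  # floor on simulated death counts so rates stay positive


def gompertz_makeham(ages: np.ndarray, c: float, a: float, b: float) -> np.ndarray:
    """Baseline hazard ``m(x) = c + a * exp(b * x)``."""
    if c < 0:
        raise DomainError("makeham term c must be >= 0")
    if a <= 0 or b <= 0:
        raise DomainError("gompertz parameters a and b must be > 0")
    ages = np.asarray(ages, dtype=float)
    return c + a * np.exp(b * ages)


@dataclass(frozen=True)
class RegimeShock:
    """Additive shock (percent) to the improvement field on a
    rectangular (year, age) window, both ranges inclusive."""

    year_from: int
    year_to: int
    age_from: int
    age_to: int
    shock: float


@dataclass(frozen=True)
class ScenarioConfig:
    ages: tuple[int, int] = (0, 110)
    n_years: int = 60
    start_year: int = 1950
    # baseline schedule
    makeham: float = 2e-4
    gompertz_level: float = 3e-5
    gompertz_slope: float = 0.095
    infant_level: float = 0.02
    infant_decay: float = 1.5
    # improvement field
    peak_level: float = 3.0
    peak_age_start: float = 40.0
    peak_age_end: float = 70.0
    bandwidth: float = 30.0
    floor_level: float = 0.3
    regimes: tuple[RegimeShock, ...] = ()
    # observation model
    exposure: float = 1e5
    noise: str = "poisson"
    #: sd (percent) of iid latent year-to-year wobble added to the
    #: improvement field itself; this is *process* noise that persists
    #: in the latent rates, unlike the Poisson observation noise
    process_noise_sd: float = 0.0
    # reference coupling
    n_references: int = 0
    reference_lag: int = 10
    reference_attenuation: float = 1.0
    seed: int | None = None

    def validate(self) -> None:
        lo, hi = self.ages
        if lo >= hi:
            raise ConfigError("ages must be an increasing (low, high) pair")
        if self.n_years < 2:
            raise ConfigError("n_years must be >= 2")
        if self.noise not in ("none", "poisson"):
            raise ConfigError(f"noise must be 'none' or 'poisson', got {self.noise!r}")
        if self.exposure <= 0:
            raise ConfigError("exposure must be > 0")
        years = self.year_vector()
        for r in self.regimes:
            if not (years[0] <= r.year_from <= r.year_to <= years[-1]):
                raise ConfigError(
                    f"regime years ({r.year_from},{r.year_to}) outside grid"
                )
            if not (lo <= r.age_from <= r.age_to <= hi):
                raise ConfigError(f"regime ages ({r.age_from},{r.age_to}) outside grid")

    def age_vector(self) -> np.ndarray:
        return np.arange(self.ages[0], self.ages[1] + 1)

    def year_vector(self) -> np.ndarray:
        return self.start_year + np.arange(self.n_years)


@dataclass
class ScenarioTruth:
    """Latent (noise-free) rates and improvement field of a scenario."""

    ages: np.ndarray
    years: np.ndarray
    rates: np.ndarray  # (n_ages, n_years)
    rho: np.ndarray  # (n_ages, n_years - 1), percent, years[1:]

    def e0(self) -> np.ndarray:
        """Per-year life expectancy at birth of the latent rates."""
        return e0_from_rates(self.rates.T)


@dataclass
class ScenarioData:
    target: MortalitySurface
    references: list[MortalitySurface]
    truth: ScenarioTruth
    reference_truths: list[ScenarioTruth]
    config: ScenarioConfig


def _baseline(cfg: ScenarioConfig) -> np.ndarray:
    x = cfg.age_vector().astype(float)
    m = gompertz_makeham(x, cfg.makeham, cfg.gompertz_level, cfg.gompertz_slope)
    if cfg.infant_level > 0:
        m = m + cfg.infant_level * np.exp(-cfg.infant_decay * x)
    return m


def _improvement_field(cfg: ScenarioConfig) -> np.ndarray:
    """Latent rho(x, t) in percent for t = years[1:]."""
    x = cfg.age_vector().astype(float)
    years = cfg.year_vector()
    frac = (np.arange(1, cfg.n_years) - 1) / max(cfg.n_years - 2, 1)
    peak_age = cfg.peak_age_start + (cfg.peak_age_end - cfg.peak_age_start) * frac
    rho = cfg.floor_level + (cfg.peak_level - cfg.floor_level) * np.exp(
        -0.5 * ((x[:, None] - peak_age[None, :]) / cfg.bandwidth) ** 2
    )
    for r in cfg.regimes:
        ymask = (years[1:] >= r.year_from) & (years[1:] <= r.year_to)
        amask = (x >= r.age_from) & (x <= r.age_to)
        rho[np.ix_(amask, ymask)] += r.shock
    if np.any(rho >= 100.0):
        raise ConfigError("improvement field reaches >= 100 %; rates would vanish")
    return rho


def _cumulate(baseline: np.ndarray, rho: np.ndarray) -> np.ndarray:
    """Latent rates from baseline column and improvement field."""
    factors = np.concatenate(
        [np.ones((len(baseline), 1)), np.cumprod(1.0 - rho / 100.0, axis=1)], axis=1
    )
    return baseline[:, None] * factors


def _observe(
    latent: np.ndarray,
    cfg: ScenarioConfig,
    rng: np.random.Generator,
    code: str,
    sex: str = "total",
) -> MortalitySurface:
    exposures = np.full(latent.shape, float(cfg.exposure))
    if cfg.noise == "poisson":
        deaths = rng.poisson(exposures * latent).astype(float)
        deaths = np.maximum(deaths, MIN_DEATHS)
        rates = deaths / exposures
    else:
        rates = latent.copy()
        deaths = exposures * rates
    return MortalitySurface(
        population_code=code,
        sex=sex,
        ages=cfg.age_vector(),
        years=cfg.year_vector(),
        rates=rates,
        deaths=deaths,
        exposures=exposures,
        open_interval=True,
    )


def generate_scenario(cfg: ScenarioConfig) -> ScenarioData:
    """Generate target and reference surfaces plus the latent truth.

    Deterministic for a fixed config (including seed): identical calls
    return bit-identical output.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    baseline = _baseline(cfg)
    field = _improvement_field(cfg)
    rho = field
    if cfg.process_noise_sd > 0:
        rho = field + cfg.process_noise_sd * rng.standard_normal(field.shape)
        if np.any(rho >= 100.0):
            raise ConfigError("process noise drove the improvement field >= 100 %")
    latent = _cumulate(baseline, rho)
    truth = ScenarioTruth(
        ages=cfg.age_vector(), years=cfg.year_vector(), rates=latent, rho=rho
    )
    target = _observe(latent, cfg, rng, code="TGT")

    references: list[MortalitySurface] = []
    ref_truths: list[ScenarioTruth] = []
    n_rho = rho.shape[1]
    for i in range(cfg.n_references):
        # reference leads the target by `lag` years on the same
        # (deterministic) field, with its own process noise
        idx = np.clip(np.arange(n_rho) + cfg.reference_lag, 0, n_rho - 1)
        rho_ref = cfg.reference_attenuation * field[:, idx]
        if cfg.process_noise_sd > 0:
            rho_ref = rho_ref + cfg.process_noise_sd * rng.standard_normal(
                rho_ref.shape
            )
        latent_ref = _cumulate(baseline, rho_ref)
        ref_truths.append(
            ScenarioTruth(
                ages=cfg.age_vector(),
                years=cfg.year_vector(),
                rates=latent_ref,
                rho=rho_ref,
            )
        )
        references.append(_observe(latent_ref, cfg, rng, code=f"REF{i + 1}"))
    return ScenarioData(
        target=target,
        references=references,
        truth=truth,
        reference_truths=ref_truths,
        config=cfg,
    )


# ---------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------

def preset(name: str, seed: int | None = None, **overrides) -> ScenarioConfig:
    """Named scenario presets.

    ``regular``: steady decline with an age-drifting improvement peak.
    ``stagnation-recovery``: improvements stall over the late base
    period, then resume; a reference population is 12 years ahead, so
    its base-period trend already shows the recovery.
    ``crisis-recovery``: a sharp working-age mortality shock early in
    the forecast window followed by recovery, with leading references.
    """
    years = 60
    start = 1950
    if name == "regular":
        cfg = ScenarioConfig(seed=seed, process_noise_sd=1.2)
    elif name == "stagnation-recovery":
        cfg = ScenarioConfig(
            seed=seed,
            peak_level=2.5,
            regimes=(
                # improvements stall over the whole base period ...
                RegimeShock(start + 10, start + 40, 0, 110, -2.0),
                # ... and resume in the forecast window
                RegimeShock(start + 41, start + years - 1, 0, 110, 0.5),
            ),
            n_references=1,
            reference_lag=12,
            reference_attenuation=1.0,
        )
    elif name == "crisis-recovery":
        cfg = ScenarioConfig(
            seed=seed,
            regimes=(
                # all ages suffer in the crisis decade, working ages most
                RegimeShock(start + 41, start + 50, 0, 110, -4.0),
                RegimeShock(start + 41, start + 50, 15, 60, -11.0),
                RegimeShock(start + 51, start + years - 1, 15, 60, 3.0),
            ),
            n_references=1,
            reference_lag=10,
        )
    else:
        raise ConfigError(f"unknown scenario preset {name!r}")
    if overrides:
        cfg = replace(cfg, **overrides)
    cfg.validate()
    return cfg
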