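"""Mortality surfaces and I/O.

A :class:`MortalitySurface` is the universal input of the pipeline: an
age x year grid of central death rates for one population and sex,
optionally accompanied by death counts and person-year exposures.

Two text dialects are supported:

* the Human Mortality Database single-age, single-year layout
  (``Mx_1x1`` style: ``Year Age Female Male Total`` columns, age token
  ``110+`` for the open interval, ``.`` for missing values);
* an internal long CSV with columns
  ``population, sex, year, age, rate[, deaths, exposure]`` used as the
  diff-able exchange format between pipeline stages.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import IO, Iterable

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    ContiguityError,
    DomainError,
    MissingDataError,
    OutOfRangeError,
    ParseError,
)

SEXES = ("female", "male", "total")

_HMD_COLUMNS = {"female": 2, "male": 3, "total": 4}


@dataclass
class MortalitySurface:
    """Age x year grid of central death rates for one population and sex.

    Parameters
    ----------
    population_code
        Short identifier, e.g. ``"HUN"``.
    sex
        One of ``"female"``, ``"male"``, ``"total"``.
    ages
        Contiguous integer ages, strictly increasing by 1.
    years
        Contiguous calendar years, strictly increasing by 1.
    rates
        Matrix ``m(x, t)`` of central death rates per person-year,
        indexed ``[age, year]``.
    deaths, exposures
        Optional matching matrices of death counts (>= 0) and
        person-years of exposure (> 0).
    open_interval
        Whether the last age is an open interval (e.g. ``110+``).
    """

    population_code: str
    sex: str
    ages: np.ndarray
    years: np.ndarray
    rates: np.ndarray
    deaths: np.ndarray | None = None
    exposures: np.ndarray | None = None
    open_interval: bool = True

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=int)
        self.years = np.asarray(self.years, dtype=int)
        if self.rates is None and self.deaths is not None and self.exposures is not None:
            self.rates = self.deaths / self.exposures
        self.rates = np.asarray(self.rates, dtype=float)
        if self.deaths is not None:
            self.deaths = np.asarray(self.deaths, dtype=float)
        if self.exposures is not None:
            self.exposures = np.asarray(self.exposures, dtype=float)
        self.validate()

    # -- validation ---------------------------------------------------

    def validate(self) -> None:
        if self.sex not in SEXES:
            raise DomainError(f"sex must be one of {SEXES}, got {self.sex!r}")
        for name, axis in (("ages", self.ages), ("years", self.years)):
            if axis.ndim != 1 or len(axis) == 0:
                raise DomainError(f"{name} must be a nonempty 1-d vector")
            if len(axis) > 1 and not np.all(np.diff(axis) == 1):
                raise ContiguityError(f"{name} must increase strictly by 1")
        shape = (len(self.ages), len(self.years))
        if self.rates.shape != shape:
            raise DomainError(
                f"rates shape {self.rates.shape} != (n_ages, n_years) {shape}"
            )
        if not np.all(np.isfinite(self.rates)) or np.any(self.rates <= 0):
            raise DomainError("all rates must be finite and > 0")
        for name, mat in (("deaths", self.deaths), ("exposures", self.exposures)):
            if mat is not None and mat.shape != shape:
                raise DomainError(f"{name} shape {mat.shape} != {shape}")
        if self.deaths is not None and np.any(self.deaths < 0):
            raise DomainError("deaths must be >= 0")
        if self.exposures is not None and np.any(self.exposures <= 0):
            raise DomainError("exposures must be > 0")
        if self.deaths is not None and self.exposures is not None:
            if np.max(np.abs(self.rates - self.deaths / self.exposures)) > 1e-12:
                raise DomainError("rates inconsistent with deaths/exposures")

    # -- convenience --------------------------------------------------

    @property
    def n_ages(self) -> int:
        return len(self.ages)

    @property
    def n_years(self) -> int:
        return len(self.years)

    def year_index(self, year: int) -> int:
        if year < self.years[0] or year > self.years[-1]:
            raise OutOfRangeError(
                f"year {year} outside available {self.years[0]}-{self.years[-1]}"
            )
        return int(year - self.years[0])

    def jumpoff_rates(self) -> np.ndarray:
        """Rates of the last observed year (the jump-off column)."""
        return self.rates[:, -1].copy()

    def log_rates(self) -> np.ndarray:
        return np.log(self.rates)


def subset_surface(
    s: MortalitySurface,
    year_range: tuple[int, int] | None = None,
    age_range: tuple[int, int] | None = None,
) -> MortalitySurface:
    """Extract an inclusive (year, age) window of a surface.

    Raises
    ------
    OutOfRangeError
        If the requested window is not contained in ``s``; the message
        lists the available bounds.
    """
    y0, y1 = year_range if year_range is not None else (s.years[0], s.years[-1])
    a0, a1 = age_range if age_range is not None else (s.ages[0], s.ages[-1])
    if y0 > y1 or a0 > a1:
        raise DomainError("range pairs must be (low, high) with low <= high")
    if y0 < s.years[0] or y1 > s.years[-1]:
        raise OutOfRangeError(
            f"years ({y0},{y1}) outside available ({s.years[0]},{s.years[-1]})"
        )
    if a0 < s.ages[0] or a1 > s.ages[-1]:
        raise OutOfRangeError(
            f"ages ({a0},{a1}) outside available ({s.ages[0]},{s.ages[-1]})"
        )
    yi = slice(int(y0 - s.years[0]), int(y1 - s.years[0]) + 1)
    ai = slice(int(a0 - s.ages[0]), int(a1 - s.ages[0]) + 1)
    return MortalitySurface(
        population_code=s.population_code,
        sex=s.sex,
        ages=s.ages[ai],
        years=s.years[yi],
        rates=s.rates[ai, yi],
        deaths=None if s.deaths is None else s.deaths[ai, yi],
        exposures=None if s.exposures is None else s.exposures[ai, yi],
        open_interval=bool(s.open_interval and a1 == s.ages[-1]),
    )


# ---------------------------------------------------------------------
# HMD 1x1 dialect
# ---------------------------------------------------------------------

def parse_hmd_table(
    text: str | IO[str],
    sex: str,
    population_code: str = "",
) -> MortalitySurface:
    """Parse an HMD 1x1 table (``Year Age Female Male Total``).

    The first two lines are treated as header/blank and skipped. The age
    token ``110+`` maps to integer age 110 with the open-interval flag
    set. Rows may appear in any order; the result is ordered by
    (year, age). A missing value (``.``) in the requested sex column is
    a hard error naming the (year, age) cell.
    """
    if sex not in SEXES:
        raise DomainError(f"sex must be one of {SEXES}, got {sex!r}")
    if hasattr(text, "read"):
        text = text.read()
    lines = io.StringIO(text).readlines()
    col = _HMD_COLUMNS[sex]
    records: list[tuple[int, int, float]] = []
    open_interval = False
    for lineno, line in enumerate(lines[2:], start=3):
        tokens = line.split()
        if not tokens:
            continue
        if not records and not tokens[0].lstrip("-").isdigit():
            # column-header line (e.g. "Year Age Female Male Total")
            continue
        if len(tokens) != 5:
            raise ParseError(
                f"line {lineno}: expected 5 columns (Year Age Female Male Total), "
                f"got {len(tokens)}"
            )
        try:
            year = int(tokens[0])
        except ValueError as exc:
            raise ParseError(f"line {lineno}: bad year token {tokens[0]!r}") from exc
        age_tok = tokens[1]
        if age_tok.endswith("+"):
            open_interval = True
            age_tok = age_tok[:-1]
        try:
            age = int(age_tok)
        except ValueError as exc:
            raise ParseError(f"line {lineno}: bad age token {tokens[1]!r}") from exc
        value_tok = tokens[col]
        if value_tok == ".":
            raise MissingDataError(
                f"missing {sex} value at (year {year}, age {age})"
            )
        try:
            value = float(value_tok)
        except ValueError as exc:
            raise ParseError(
                f"line {lineno}: bad {sex} value {value_tok!r}"
            ) from exc
        records.append((year, age, value))
    if not records:
        raise ParseError("no data rows found")
    records.sort()
    years = np.unique([r[0] for r in records])
    ages = np.unique([r[1] for r in records])
    if len(years) > 1 and not np.all(np.diff(years) == 1):
        raise ContiguityError(f"years not contiguous: {years.tolist()}")
    if len(ages) > 1 and not np.all(np.diff(ages) == 1):
        raise ContiguityError(f"ages not contiguous: {ages.tolist()}")
    rates = np.full((len(ages), len(years)), np.nan)
    for year, age, value in records:
        rates[age - ages[0], year - years[0]] = value
    if np.any(np.isnan(rates)):
        ai, yi = np.argwhere(np.isnan(rates))[0]
        raise MissingDataError(
            f"no row for (year {years[yi]}, age {ages[ai]})"
        )
    return MortalitySurface(
        population_code=population_code,
        sex=sex,
        ages=ages,
        years=years,
        rates=rates,
        open_interval=open_interval,
    )


def format_hmd_table(surfaces: dict[str, MortalitySurface]) -> str:
    """Render female/male/total surfaces back into the HMD 1x1 layout.

    Inverse of :func:`parse_hmd_table` on the numeric content; any of
    the three sex columns may be omitted (written as ``.``).
    """
    ref = next(iter(surfaces.values()))
    out = ["Mx_1x1 (lexcast)", ""]
    out.append(f"{'Year':>6} {'Age':>6} {'Female':>12} {'Male':>12} {'Total':>12}")
    for yi, year in enumerate(ref.years):
        for ai, age in enumerate(ref.ages):
            age_tok = f"{age}+" if (ref.open_interval and ai == ref.n_ages - 1) else str(age)
            cells = []
            for sx in ("female", "male", "total"):
                s = surfaces.get(sx)
                cells.append("." if s is None else format(s.rates[ai, yi], ".17g"))
            out.append(
                f"{year:>6} {age_tok:>6} {cells[0]:>12} {cells[1]:>12} {cells[2]:>12}"
            )
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------
# internal long CSV
# ---------------------------------------------------------------------

def write_long_csv(s: MortalitySurface, path_or_buf) -> None:
    """Write a surface to the internal long CSV exchange format."""
    ages, years = np.meshgrid(s.ages, s.years, indexing="ij")
    data = {
        "population": s.population_code,
        "sex": s.sex,
        "year": years.ravel(),
        "age": ages.ravel(),
        "rate": s.rates.ravel(),
    }
    if s.deaths is not None:
        data["deaths"] = s.deaths.ravel()
    if s.exposures is not None:
        data["exposure"] = s.exposures.ravel()
    df = pd.DataFrame(data)
    df.to_csv(path_or_buf, index=False, float_format="%.17g")


def read_long_csv(path_or_buf, open_interval: bool = True) -> MortalitySurface:
    """Read a surface from the internal long CSV exchange format."""
    df = pd.read_csv(path_or_buf, float_precision="round_trip")
    required = {"population", "sex", "year", "age", "rate"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"long CSV missing columns: {sorted(missing)}")
    pops = df["population"].unique()
    sexes = df["sex"].unique()
    if len(pops) != 1 or len(sexes) != 1:
        raise ParseError("long CSV must contain exactly one (population, sex)")
    df = df.sort_values(["year", "age"])
    years = np.sort(df["year"].unique())
    ages = np.sort(df["age"].unique())
    shape = (len(ages), len(years))

    def pivot(col: str) -> np.ndarray:
        mat = np.full(shape, np.nan)
        mat[df["age"] - ages[0], df["year"] - years[0]] = df[col].to_numpy()
        if np.any(np.isnan(mat)):
            ai, yi = np.argwhere(np.isnan(mat))[0]
            raise MissingDataError(f"no {col} for (year {years[yi]}, age {ages[ai]})")
        return mat

    return MortalitySurface(
        population_code=str(pops[0]),
        sex=str(sexes[0]),
        ages=ages,
        years=years,
        rates=pivot("rate"),
        deaths=pivot("deaths") if "deaths" in df.columns else None,
        exposures=pivot("exposure") if "exposure" in df.columns else None,
        open_interval=open_interval,
    )


def check_aligned(surfaces: Iterable[MortalitySurface]) -> None:
    """Raise AlignmentError unless all surfaces share one age/year grid."""
    surfaces = list(surfaces)
    ref = surfaces[0]
    for s in surfaces[1:]:
        if not (np.array_equal(s.ages, ref.ages) and np.array_equal(s.years, ref.years)):
            raise AlignmentError(
                f"surface {s.population_code!r} grid differs from {ref.population_code!r}"
            )
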