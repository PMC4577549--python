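"""Quantile tables, report arithmetic, plots, and the pipeline driver.

A :class:`QuantileTable` holds e0 quantiles keyed by (population, sex,
quantile level) with calendar years as columns — the layout used for
published forecast summaries. Interval widths and median gains are
computed from it, optionally rounded half-away-from-zero to integer
years (the convention used in prose); raw values are always retained
in the CSVs.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluation, lee_carter, li_lee, rmi, synthetic
from .data_io import MortalitySurface, read_long_csv, write_long_csv
from .errors import ConfigError, TableLookupError
from .improvement import ImprovementSurface, improvement_rates
from .lifetable import e0_series
from .results import ForecastResult

KEY = ["population", "sex", "quantile"]


def round_half_away(x: float) -> int:
    """Round to the nearest integer, ties away from zero."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


@dataclass
class QuantileTable:
    """e0 quantiles: rows (population, sex, quantile level), year columns."""

    frame: pd.DataFrame  # MultiIndex rows, integer year columns

    def __post_init__(self) -> None:
        self.frame = self.frame.copy()
        self.frame.columns = self.frame.columns.astype(int)

    def value(self, population: str, sex: str, quantile: float, year: int) -> float:
        try:
            return float(self.frame.loc[(population, sex, quantile), int(year)])
        except KeyError as exc:
            raise TableLookupError(
                f"no entry for ({population}, {sex}, {quantile}, {year})"
            ) from exc

    @classmethod
    def from_results(cls, results: list[ForecastResult]) -> "QuantileTable":
        rows = []
        for r in results:
            for level in r.levels:
                rows.append(
                    pd.Series(
                        r.e0_quantiles.loc[level].to_numpy(),
                        index=r.e0_quantiles.columns,
                        name=(r.population_code, r.sex, level),
                    )
                )
        frame = pd.DataFrame(rows)
        frame.index = pd.MultiIndex.from_tuples(frame.index, names=KEY)
        return cls(frame)

    # -- CSV round trip ------------------------------------------------

    def to_csv(self, path_or_buf) -> None:
        out = self.frame.reset_index()
        out.to_csv(path_or_buf, index=False, float_format="%.17g")

    @classmethod
    def read_csv(cls, path_or_buf) -> "QuantileTable":
        df = pd.read_csv(path_or_buf)
        missing = set(KEY) - set(df.columns)
        if missing:
            raise ConfigError(f"quantile CSV missing columns {sorted(missing)}")
        df = df.set_index(KEY)
        return cls(df)


def interval_width(
    q: QuantileTable,
    population: str,
    sex: str,
    year: int,
    level_low: float,
    level_high: float,
    rounding: str = "none",
) -> float | int:
    """Prediction-interval width value(high) - value(low) in years."""
    if level_high < level_low:
        raise ConfigError("level_high must not be below level_low")
    width = q.value(population, sex, level_high, year) - q.value(
        population, sex, level_low, year
    )
    return round_half_away(width) if rounding == "integer" else width


def e0_gain(
    q: QuantileTable,
    population: str,
    sex: str,
    year_from: int,
    year_to: int,
    level: float = 0.5,
    rounding: str = "none",
) -> float | int:
    """Gain in e0 at a quantile level between two years."""
    gain = q.value(population, sex, level, year_to) - q.value(
        population, sex, level, year_from
    )
    return round_half_away(gain) if rounding == "integer" else gain


# ---------------------------------------------------------------------
# plots (visual only; no numeric assertions depend on these)
# ---------------------------------------------------------------------

BAND_COLORS = {
    "strong": "#d7301f",
    "moderate": "#31a354",
    "stagnating": "#f7f7f7",
    "deteriorating": "#525252",
}


def lexis_band_map(surface: ImprovementSurface, path: str | Path) -> None:
    """Heat map of improvement bands on the Lexis plane."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    if surface.band is None:
        surface.classify()
    order = ["deteriorating", "stagnating", "moderate", "strong"]
    codes = np.vectorize(order.index)(surface.band)
    fig, ax = plt.subplots(figsize=(7, 5))
    ax.pcolormesh(
        surface.years,
        surface.ages,
        codes,
        cmap=ListedColormap([BAND_COLORS[b] for b in order]),
        vmin=-0.5,
        vmax=3.5,
    )
    ax.set_xlabel("year")
    ax.set_ylabel("age")
    ax.set_title("improvement bands")
    fig.savefig(path, dpi=120)
    plt.close(fig)


def fan_chart(
    result: ForecastResult,
    observed_e0: pd.Series | None,
    path: str | Path,
) -> None:
    """e0 fan chart with 80/67/50 % bands shading toward the median."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    years = result.e0_quantiles.columns
    for lo, hi, alpha in ((0.10, 0.90, 0.2), (0.165, 0.835, 0.35), (0.25, 0.75, 0.5)):
        if lo in result.levels and hi in result.levels:
            ax.fill_between(
                years,
                result.e0_quantiles.loc[lo],
                result.e0_quantiles.loc[hi],
                color="tab:blue",
                alpha=alpha,
                linewidth=0,
            )
    ax.plot(years, result.e0_quantiles.loc[0.5], "--", color="tab:blue", label="median")
    if observed_e0 is not None:
        ax.plot(observed_e0.index, observed_e0, color="black", label="observed")
    ax.set_xlabel("year")
    ax.set_ylabel("e0 (years)")
    ax.legend()
    ax.set_title(f"{result.population_code} ({result.sex})")
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------
# config-driven pipeline
# ---------------------------------------------------------------------

def _require(config: dict, key: str):
    if key not in config:
        raise ConfigError(f"missing config key {key!r}")
    return config[key]


def _load_data(config: dict):
    """Returns (target surface, references list, truth-or-None)."""
    data = _require(config, "data")
    if "preset" in data:
        cfg = synthetic.preset(
            data["preset"],
            seed=data.get("seed"),
            **data.get("overrides", {}),
        )
        scen = synthetic.generate_scenario(cfg)
        return scen.target, scen.references, scen
    if "long_csv" in data:
        target = read_long_csv(data["long_csv"])
        refs = [read_long_csv(p) for p in data.get("reference_csvs", [])]
        return target, refs, None
    raise ConfigError("missing config key 'data.preset' or 'data.long_csv'")


def _rmi_config(config: dict) -> rmi.RMIConfig:
    overrides = dict(config.get("rmi", {}))
    valid = {f.name for f in dataclasses.fields(rmi.RMIConfig)}
    bad = set(overrides) - valid
    if bad:
        raise ConfigError(f"unknown rmi config keys {sorted(bad)}")
    return rmi.RMIConfig(**overrides)


def run_pipeline(config_path: str | Path, out_dir: str | Path | None = None) -> dict:
    """Run a full simulate/fit/forecast/evaluate/report cycle.

    The YAML config names a data source, a design (retrospective or
    prospective), a model list, and seeds. Outputs (CSV tables, plots,
    and a resolved-parameter run log) land in ``out_dir``; identical
    config + seed gives byte-identical numeric CSVs.
    """
    config_path = Path(config_path)
    with open(config_path) as fh:
        config = yaml.safe_load(fh)
    out = Path(out_dir if out_dir is not None else _require(config, "out_dir"))
    out.mkdir(parents=True, exist_ok=True)

    target, references, scen = _load_data(config)
    design = _require(config, "design")
    models = list(_require(config, "models"))
    unknown = [m for m in models if m not in evaluation.MODEL_REGISTRY]
    if unknown:
        raise ConfigError(f"unknown model name(s) {unknown}")
    n_draws = int(config.get("n_draws", 500))
    seed = config.get("seed")
    rmi_config = _rmi_config(config)
    bundle: dict = {"config": config, "out_dir": str(out)}

    # improvement-band Lexis map of the input data
    imp = improvement_rates(target).classify()
    imp.to_frame().to_csv(
        out / "improvement_surface.csv", index=False, float_format="%.17g"
    )
    if config.get("plots", True):
        lexis_band_map(imp, out / "improvement_bands.png")

    refs_map = {name: references for name in models}
    if design == "retrospective":
        base = tuple(_require(config, "base"))
        horizon_end = int(_require(config, "horizon_end"))
        report = evaluation.run_retrospective(
            target,
            references=refs_map,
            base=base,
            horizon_end=horizon_end,
            models=models,
            n_draws=n_draws,
            seed=seed,
            model_options={"rmi": {"config": rmi_config}},
        )
        report.fe_frame().to_csv(
            out / "forecast_errors.csv", index=False, float_format="%.17g"
        )
        report.mae_frame().to_csv(
            out / "mae_summary.csv", index=False, float_format="%.17g"
        )
        (out / "summary.txt").write_text(report.summary_text() + "\n")
        bundle["report"] = report
    elif design == "prospective":
        base = tuple(_require(config, "base"))
        horizon = int(_require(config, "horizon"))
        from .data_io import subset_surface

        base_surface = subset_surface(target, year_range=base)
        base_refs = [subset_surface(r, year_range=base) for r in references]
        results = []
        for name in models:
            fn = evaluation.MODEL_REGISTRY[name]
            opts = {"config": rmi_config} if name == "rmi" else {}
            result = fn(
                base_surface, base_refs, horizon=horizon, n_draws=n_draws,
                seed=seed, **opts,
            )
            result.e0_long_frame().to_csv(
                out / f"e0_quantiles_{name}.csv", index=False, float_format="%.17g"
            )
            if config.get("plots", True):
                fan_chart(result, e0_series(target), out / f"fan_{name}.png")
            results.append(result)
            # one table per model: the key is (population, sex, quantile)
            QuantileTable.from_results([result]).to_csv(
                out / f"e0_quantile_table_{name}.csv"
            )
        bundle["results"] = results
        bundle["quantile_tables"] = {
            name: QuantileTable.from_results([r])
            for name, r in zip(models, results)
        }
    else:
        raise ConfigError(
            f"design must be 'retrospective' or 'prospective', got {design!r}"
        )

    if scen is not None:
        write_long_csv(scen.target, out / "target_surface.csv")
        for r in scen.references:
            write_long_csv(r, out / f"reference_{r.population_code}.csv")
    log = {
        "config_file": str(config_path),
        "resolved": {
            "design": design,
            "models": models,
            "n_draws": n_draws,
            "seed": seed,
            "rmi_config": dataclasses.asdict(rmi_config),
        },
    }
    with open(out / "run_log.yaml", "w") as fh:
        yaml.safe_dump(log, fh)
    return bundle
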