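# lexcast

Mortality forecasting on Lexis surfaces: period life tables and life
expectancy at birth, rates of mortality improvement with band
classification and two-dimensional P-spline smoothing, the classic
log-bilinear (SVD + random-walk-with-drift) model and its coherent
multi-population variant, a probabilistic improvement-rate forecaster
with optional reference-trend blending, a retrospective
forecast-evaluation harness, and a synthetic scenario generator that
emulates regular, stagnation–recovery, and crisis–recovery mortality
regimes.

## Layout

| module | contents |
| --- | --- |
| `lexcast.data_io` | `MortalitySurface`, HMD 1×1 parser, long-CSV exchange format, subsetting |
| `lexcast.lifetable` | period life tables, `e0_series`, vectorized `e0_from_rates` |
| `lexcast.improvement` | improvement rates ρ(x,t), band classification, penalized B-spline smoothing |
| `lexcast.lee_carter` | log-bilinear fit (SVD) and stochastic forecast |
| `lexcast.li_lee` | coherent multi-population fit (common factor + AR(1) deviations) |
| `lexcast.rmi` | improvement-rate trend model, reference blending, bootstrap predictive simulation |
| `lexcast.evaluation` | retrospective designs, forecast errors, MAE, typed failure capture |
| `lexcast.synthetic` | Gompertz–Makeham baselines, regime shocks, Poisson observation, presets |
| `lexcast.reporting` | quantile tables, interval widths/gains, fan charts, Lexis maps, config pipeline |

The improvement-rate forecaster is a documented reconstruction: for
each age a linear time trend of ρ(x,t) is fit jointly across ages with
an order-2 smoothness penalty and per-age precision weights; a pooled
reference trend is blended in with weight `w(h) = w_max·(1−exp(−h/τ))`;
uncertainty comes from a residual bootstrap over years plus per-age
Gaussian improvement noise, cumulated multiplicatively from the
jump-off rates. All constants live in `RMIConfig` and are echoed into
outputs.

## CLI

```sh
lexcast simulate stagnation-recovery --seed 3 --out-dir scratch/sim
lexcast import-hmd Mx_1x1.txt --sex female --population ESP --out esp_f.csv
lexcast e0 esp_f.csv
lexcast run config.yaml --out-dir scratch/run
```

A pipeline config names a data source (scenario preset or long CSVs), a
design (`retrospective` or `prospective`), a model list, and seeds:

```yaml
data: {preset: crisis-recovery, seed: 5}
design: retrospective
base: [1965, 1990]
horizon_end: 2009
models: [lee_carter, li_lee, rmi]
n_draws: 500
seed: 1
```

Identical config + seed reproduces byte-identical numeric CSVs.

## Data fixtures

* `data/prospective_e0_quantiles.csv` — transcription of the published
  prospective e0 quantiles (0.025/0.5/0.975 for Spain, Hungary, Russia,
  2010–2050), used by the reporting arithmetic.
* `data/reference_assignments.yaml` — the published reference-country
  assignments for retrospective and prospective designs; data, not code.

Observed-value comparisons against mortality databases are
vintage-dependent and are deliberately not part of the test suite; the
pipeline accepts HMD 1×1 text directly via `lexcast import-hmd` for
such workflows.
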