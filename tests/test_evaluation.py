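import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lexcast.data_io import subset_surface
from lexcast.errors import AlignmentError, DegenerateFitError, DomainError
from lexcast.evaluation import (
    EvaluationReport,
    forecast_errors,
    mae,
    run_retrospective,
)
from lexcast.lifetable import e0_series
from lexcast.results import ForecastResult
from lexcast.rmi import RMIConfig
from lexcast.synthetic import generate_scenario, preset


def series(values, first_year=1991):
    idx = pd.Index(np.arange(first_year, first_year + len(values)), name="year")
    return pd.Series(values, index=idx)


class TestForecastErrors:
    def test_perfect_forecast_zero(self):
        obs = series([70.0, 70.5, 71.0])
        assert (forecast_errors(obs, obs) == 0).all()

    def test_overestimate_positive(self):
        obs = series([70.0, 70.5])
        fc = obs + 0.5
        np.testing.assert_allclose(forecast_errors(fc, obs), 0.5)

    def test_antisymmetry(self):
        a = series([70.0, 71.0, 69.5])
        b = series([70.2, 70.4, 70.1])
        np.testing.assert_allclose(
            forecast_errors(a, b), -forecast_errors(b, a)
        )

    def test_grid_mismatch(self):
        with pytest.raises(AlignmentError):
            forecast_errors(series([1.0, 2.0]), series([1.0, 2.0], first_year=1990))


class TestMae:
    def test_example(self):
        assert mae([0.5, -0.5, 1.0]) == pytest.approx(2.0 / 3.0)

    def test_all_zero(self):
        assert mae([0.0, 0.0]) == 0.0

    def test_empty_error(self):
        with pytest.raises(DomainError):
            mae([])

    @settings(max_examples=30, deadline=None)
    @given(
        st.lists(st.floats(-5, 5, allow_nan=False), min_size=1, max_size=20),
        st.integers(0, 2**20),
    )
    def test_sign_flip_invariance_and_jensen(self, errors, mask_bits):
        errors = np.asarray(errors)
        signs = np.where(
            [(mask_bits >> i) & 1 for i in range(len(errors))], -1.0, 1.0
        )
        assert mae(errors * signs) == pytest.approx(mae(errors))
        assert mae(errors) <= np.max(np.abs(errors)) + 1e-12
        assert mae(errors) >= abs(np.mean(errors)) - 1e-12


@pytest.fixture(scope="module")
def crisis_scenario():
    return generate_scenario(preset("crisis-recovery", seed=17))


def perfect_foresight_factory(observed):
    """Oracle model: returns the observed rates of the horizon years."""

    def perfect_foresight(base, refs, horizon, n_draws, seed, **opts):
        future = subset_surface(
            observed, year_range=(base.years[-1] + 1, base.years[-1] + horizon)
        )
        draws = np.repeat(future.rates[None, :, :], 2, axis=0)
        return ForecastResult.from_rate_draws(
            population_code=base.population_code,
            sex=base.sex,
            ages=future.ages,
            years=future.years,
            rate_draws=draws,
            seed=seed,
        )

    return perfect_foresight


def failing_model(base, refs, horizon, n_draws, seed, **opts):
    raise DegenerateFitError("synthetic failure")


class TestRunRetrospective:
    def test_scored_year_count(self, crisis_scenario):
        report = run_retrospective(
            crisis_scenario.target,
            base=(1965, 1990),
            horizon_end=2009,
            models=("lee_carter",),
            n_draws=50,
            seed=0,
        )
        row = report.row("lee_carter")
        assert row.status == "ok"
        assert len(row.fe) == 19
        assert row.fe.index[0] == 1991 and row.fe.index[-1] == 2009

    def test_sensitivity_base_echoed(self, crisis_scenario):
        report = run_retrospective(
            crisis_scenario.target,
            base=(1975, 1990),
            horizon_end=2009,
            models=("lee_carter",),
            n_draws=50,
            seed=0,
        )
        assert report.base == (1975, 1990)

    def test_perfect_foresight_zero_mae(self, crisis_scenario):
        model = perfect_foresight_factory(crisis_scenario.target)
        report = run_retrospective(
            crisis_scenario.target,
            base=(1965, 1990),
            horizon_end=2009,
            models=(model,),
            n_draws=10,
            seed=0,
        )
        assert report.rows[0].mae == pytest.approx(0.0, abs=1e-9)

    def test_failure_recorded_without_aborting(self, crisis_scenario):
        model = perfect_foresight_factory(crisis_scenario.target)
        report = run_retrospective(
            crisis_scenario.target,
            base=(1965, 1990),
            horizon_end=2009,
            models=(failing_model, model),
            n_draws=10,
            seed=0,
        )
        statuses = {r.model: r.status for r in report.rows}
        assert statuses["failing_model"] == "error:DegenerateFitError"
        assert statuses["perfect_foresight"] == "ok"
        assert report.row("failing_model").mae is None

    def test_mae_internally_consistent(self, crisis_scenario):
        report = run_retrospective(
            crisis_scenario.target,
            base=(1965, 1990),
            horizon_end=2009,
            models=("lee_carter", "rmi"),
            n_draws=100,
            seed=1,
            model_options={"rmi": {"config": RMIConfig(seed=1, n_draws=50)}},
        )
        for row in report.rows:
            assert row.status == "ok"
            assert row.mae == pytest.approx(mae(row.fe), rel=1e-12)
            assert row.mae <= np.max(np.abs(row.fe)) + 1e-12
            assert row.mae >= abs(np.mean(row.fe)) - 1e-12

    def test_li_lee_runs_with_references(self, crisis_scenario):
        report = run_retrospective(
            crisis_scenario.target,
            references={"li_lee": crisis_scenario.references},
            base=(1965, 1990),
            horizon_end=2009,
            models=("li_lee",),
            n_draws=50,
            seed=2,
        )
        assert report.rows[0].status == "ok"

    def test_li_lee_without_references_is_error_row(self, crisis_scenario):
        report = run_retrospective(
            crisis_scenario.target,
            base=(1965, 1990),
            horizon_end=2009,
            models=("li_lee",),
            n_draws=10,
            seed=0,
        )
        assert report.rows[0].status == "error:DomainError"

    def test_horizon_beyond_data(self, crisis_scenario):
        with pytest.raises(DomainError):
            run_retrospective(
                crisis_scenario.target,
                base=(1965, 1990),
                horizon_end=2050,
                models=("lee_carter",),
            )

    def test_unknown_model_name(self, crisis_scenario):
        with pytest.raises(DomainError):
            run_retrospective(
                crisis_scenario.target,
                base=(1965, 1990),
                horizon_end=2009,
                models=("not_a_model",),
            )

    def test_frames_and_summary(self, crisis_scenario):
        model = perfect_foresight_factory(crisis_scenario.target)
        report = run_retrospective(
            crisis_scenario.target,
            base=(1965, 1990),
            horizon_end=2009,
            models=(model, failing_model),
            n_draws=10,
            seed=0,
        )
        fe = report.fe_frame()
        assert set(fe.columns) == {"population", "sex", "model", "year", "fe"}
        assert len(fe) == 19
        summary = report.mae_frame()
        assert len(summary) == 2
        text = report.summary_text()
        assert "error:DegenerateFitError" in text
        assert "MAE" in text


class TestComparativeMae:
    def test_rmi_with_reference_beats_lee_carter_mostly(self):
        """Abstract-level comparative claim at reduced replicate count;
        the full 50-replicate version lives in the acceptance suite."""
        wins = 0
        n = 8
        for rep in range(n):
            scen = generate_scenario(preset("stagnation-recovery", seed=300 + rep))
            report = run_retrospective(
                scen.target,
                references={"rmi": scen.references},
                base=(1965, 1990),
                horizon_end=2009,
                models=("lee_carter", "rmi"),
                n_draws=200,
                seed=rep,
                model_options={"rmi": {"config": RMIConfig(w_max=0.5, seed=rep)}},
            )
            if report.row("rmi").mae <= report.row("lee_carter").mae:
                wins += 1
        assert wins >= 6
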