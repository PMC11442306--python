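"""Simulation protocol, factorial attribution, sensitivity and ensemble
significance machinery."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from borealfire import experiments as ex
from borealfire.forcing import (
    LightningConfig,
    PopulationConfig,
    RainConfig,
    ScenarioConfig,
    VariableConfig,
)
from borealfire.simulate import RunProtocol, RunResult, run_simulation


def _no_trend_scenario(**kwargs):
    base = ScenarioConfig(nlat=4, nlon=4, years=4, seed=21)
    overrides = dict(
        tmax=VariableConfig(0.0, 20.0, 3.5, 0.8, 0.0, sigma_domain=1.5),
        rh=VariableConfig(70.0, -12.0, 8.0, 0.7, 0.0, sigma_domain=4.0),
        lightning=LightningConfig(trend_frac_per_century=0.0),
        co2_biomass_trend_frac_per_century=0.0,
    )
    overrides.update(kwargs)
    return dataclasses.replace(base, **overrides)


def _stub_run(rng, years=40, slope=0.0, seed_col=None):
    """Minimal RunResult with engineered annual driver/response columns."""
    t = rng.normal(1.0, 1.0, years)
    burned = slope * t + rng.normal(0.0, 0.05, years)
    df = pd.DataFrame(
        {
            "year": np.arange(years),
            "tmax_c": t,
            "rh_pct": rng.normal(70, 2, years),
            "wind_kmh": rng.normal(12, 1, years),
            "rain_mm": rng.normal(2, 0.1, years),
            "lightning_km2_yr": rng.normal(1, 0.1, years),
            "popdens_km2": np.full(years, 0.03),
            "vegc_kgC_m2": rng.normal(4, 0.1, years),
        }
    )
    return RunResult(
        year=np.arange(years),
        burned_km2=burned * 1e4,
        co2_kg=burned * 1e9,
        burned_map_km2=np.zeros((years, 1)),
        co2_map_kg=np.zeros((years, 1)),
        driver_means=df,
        scenario=ScenarioConfig(nlat=1, nlon=1, years=years),
        protocol=RunProtocol(years=years, spinup_years=0),
    )


class TestRunSimulation:
    def test_no_ignition_sources_no_fire(self):
        scenario = _no_trend_scenario(
            lightning=LightningConfig(
                annual_strikes_km2_yr=0.0, trend_frac_per_century=0.0
            ),
            population=PopulationConfig(median_km2=0.0),
        )
        r = run_simulation(RunProtocol(years=4, spinup_years=0), scenario)
        assert np.all(r.burned_km2 == 0.0)
        assert np.all(r.co2_kg == 0.0)

    def test_saturated_wet_forcing_suppresses_fire(self):
        scenario = _no_trend_scenario(
            rh=VariableConfig(100.0, 0.0, 0.0, 0.7, 0.0),
            rain=RainConfig(p_wet=1.0, mean_mm=8.0),
            rh_temp_coupling=0.0,  # keep the air saturated every day
        )
        # one spin-up year lets the moisture codes wet down from their
        # conventional dry-ish start values before recording
        r = run_simulation(RunProtocol(years=2, spinup_years=1), scenario)
        assert r.burned_km2.sum() < 1e-3  # P_m collapses when fuel stays wet

    def test_warming_scenario_increases_decadal_burned_area(self, default_run):
        first = default_run.burned_km2[:11].mean()
        last = default_run.burned_km2[-11:].mean()
        assert last > first


class TestAttribution:
    def test_trend_delta_window_arithmetic(self):
        series = np.arange(30.0)
        assert ex.trend_delta(series, window=5) == pytest.approx(25.0)
        with pytest.raises(ValueError):
            ex.trend_delta(series[:8], window=5)

    def test_single_trending_driver_takes_full_attribution(self):
        scenario = dataclasses.replace(
            _no_trend_scenario(
                lightning=LightningConfig(trend_frac_per_century=1.0)
            ),
            nlat=10,
            nlon=10,
            years=30,
            seed=3,
        )
        protocol = RunProtocol(years=30, spinup_years=3)
        full, fixed = ex.run_factorial(protocol, scenario)
        att = ex.factorial_attribution(full, fixed, window=10)
        assert att.defined
        assert att.contributions["lightning"] >= 0.95
        for d in ("climate", "co2_biomass", "population"):
            assert abs(att.contributions[d]) <= 0.05

    def test_no_trends_flagged_undefined(self):
        scenario = _no_trend_scenario(population=PopulationConfig())
        protocol = RunProtocol(years=4, spinup_years=0)
        full, fixed = ex.run_factorial(protocol, scenario)
        att = ex.factorial_attribution(full, fixed, window=2)
        assert not att.defined
        assert all(np.isnan(v) for v in att.contributions.values())

    def test_contributions_sum_to_one_when_defined(self):
        scenario = dataclasses.replace(
            _no_trend_scenario(
                lightning=LightningConfig(trend_frac_per_century=1.0)
            ),
            years=20,
            seed=6,
        )
        protocol = RunProtocol(years=20, spinup_years=1)
        full, fixed = ex.run_factorial(protocol, scenario)
        att = ex.factorial_attribution(full, fixed, window=7)
        assert sum(att.contributions.values()) == pytest.approx(1.0, abs=1e-9)


class TestSensitivity:
    def test_engineered_linear_slope_recovered(self, rng):
        runs = [_stub_run(rng, slope=1.2) for _ in range(3)]
        curves = ex.sensitivity_curves(runs, drivers=("tmax_c",))
        entry = curves["tmax_c"]
        assert entry["defined"]
        assert entry["slope"] == pytest.approx(1.2, abs=0.1)
        lo, hi = entry["ci"]
        assert lo < 1.2 < hi

    def test_constant_driver_flagged_undefined(self, rng):
        runs = [_stub_run(rng) for _ in range(2)]
        curves = ex.sensitivity_curves(runs, drivers=("popdens_km2",))
        assert not curves["popdens_km2"]["defined"]
        assert np.isnan(curves["popdens_km2"]["slope"])

    def test_point_count_is_runs_times_years(self, rng):
        runs = [_stub_run(rng, years=25) for _ in range(4)]
        curves = ex.sensitivity_curves(runs, drivers=("tmax_c",))
        assert curves["tmax_c"]["n"] == 4 * 25

    def test_single_run_rejected(self, rng):
        with pytest.raises(ValueError):
            ex.sensitivity_curves([_stub_run(rng)])


class TestEnsembleChangeTest:
    def test_identical_periods_all_no_change(self, rng):
        maps = rng.normal(1.0, 0.1, (4, 50))
        mask, _ = ex.ensemble_change_test(maps, maps.copy())
        assert mask.all()

    def test_large_shift_detected(self, rng):
        ref = rng.normal(0.0, 1.0, (5, 100))
        end = ref + 10.0  # +10 sigma everywhere
        mask, _ = ex.ensemble_change_test(ref, end)
        assert not mask.any()

    def test_type_one_error_rate_near_alpha(self, rng):
        """Under the null the no-change mask misfires at ~alpha."""
        ref = rng.normal(0.0, 1.0, (5, 10000))
        end = rng.normal(0.0, 1.0, (5, 10000))
        mask, _ = ex.ensemble_change_test(ref, end, alpha=0.05)
        assert (~mask).mean() == pytest.approx(0.05, abs=0.01)

    def test_too_few_members_rejected(self, rng):
        with pytest.raises(ValueError):
            ex.ensemble_change_test(rng.normal(size=(1, 10)), rng.normal(size=(3, 10)))


class TestVarianceDecomposition:
    def test_pure_row_effect(self):
        m = np.array([[1.0, 1.0], [3.0, 3.0]])
        frac = ex.variance_decomposition(m)
        assert frac["climate"] == pytest.approx(1.0)
        assert frac["lightning"] == pytest.approx(0.0)

    def test_additive_matrix_has_no_interaction(self, rng):
        r = rng.normal(0, 1, 4)[:, None]
        c = rng.normal(0, 1, 3)[None, :]
        frac = ex.variance_decomposition(r + c)
        assert frac["interaction"] == pytest.approx(0.0, abs=1e-12)
        assert sum(frac.values()) == pytest.approx(1.0)

    def test_degenerate_matrix_rejected(self):
        with pytest.raises(ValueError):
            ex.variance_decomposition(np.ones((1, 3)))


def test_driver_signs_match_process_expectations(ensemble_runs):
    """Across the default ensemble, burned area rises with temperature and
    lightning and falls with relative humidity and population density."""
    signs = ex.driver_sign_test(ensemble_runs)
    assert signs["tmax_c"][0] > 0
    assert signs["lightning_km2_yr"][0] > 0
    assert signs["rh_pct"][0] < 0
    assert signs["popdens_km2"][0] < 0
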