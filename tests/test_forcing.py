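"""Synthetic forcing generator, delta bias corrections and fuel regrowth."""

import dataclasses

import numpy as np
import pytest

from borealfire import forcing as fg


def _quiet_cfg(**kwargs):
    """Small grid, no noise, no trends unless overridden."""
    base = fg.ScenarioConfig(nlat=2, nlon=2, years=2, seed=5)
    overrides = {
        "tmax": fg.VariableConfig(0.0, 20.0, 0.0, 0.8, 0.0),
        "rh": fg.VariableConfig(70.0, -12.0, 0.0, 0.7, 0.0),
        "wind": fg.VariableConfig(12.0, 2.0, 0.0, 0.5, 0.0),
        "rain": fg.RainConfig(p_wet=0.0),
        "lightning": fg.LightningConfig(trend_frac_per_century=0.0, annual_sigma=0.0),
        "population": fg.PopulationConfig(),
        "co2_biomass_trend_frac_per_century": 0.0,
    }
    overrides.update(kwargs)
    return dataclasses.replace(base, **overrides)


class TestGenerator:
    def test_same_seed_is_bit_identical(self):
        cfg = fg.ScenarioConfig(nlat=3, nlon=3, years=2, seed=11)
        a = fg.generate_forcing(cfg)
        b = fg.generate_forcing(cfg)
        for name in ("tmax", "rh", "wind", "rain", "lightning"):
            np.testing.assert_array_equal(getattr(a, name), getattr(b, name))

    def test_zero_noise_zero_trend_is_pure_sinusoid(self):
        f = fg.generate_forcing(_quiet_cfg())
        doy = f.doy
        expected = 0.0 + 20.0 * np.cos(2 * np.pi * (doy - 200) / 365.0)
        np.testing.assert_allclose(f.tmax[:, 0], expected, atol=1e-12)
        assert np.all(f.rain == 0.0)

    def test_named_streams_are_independent(self):
        """Changing the lightning configuration must not perturb the weather."""
        cfg1 = fg.ScenarioConfig(nlat=3, nlon=3, years=1, seed=4)
        cfg2 = dataclasses.replace(
            cfg1, lightning=fg.LightningConfig(annual_strikes_km2_yr=5.0)
        )
        a, b = fg.generate_forcing(cfg1), fg.generate_forcing(cfg2)
        np.testing.assert_array_equal(a.tmax, b.tmax)
        np.testing.assert_array_equal(a.rain, b.rain)
        assert not np.array_equal(a.lightning, b.lightning)

    def test_configured_trend_recovered_by_regression(self):
        """A +4 degC/century trend is recovered from annual means of a
        100-year run to within 0.5."""
        cfg = dataclasses.replace(
            _quiet_cfg(tmax=fg.VariableConfig(0.0, 20.0, 3.5, 0.8, 4.0)), years=100
        )
        f = fg.generate_forcing(cfg)
        annual = np.array([f.tmax[f.year_index == y].mean() for y in range(100)])
        slope = np.polyfit(np.arange(100) / 100.0, annual, 1)[0]
        assert slope == pytest.approx(4.0, abs=0.5)

    def test_physical_ranges_respected(self):
        f = fg.generate_forcing(fg.ScenarioConfig(nlat=4, nlon=4, years=3, seed=2))
        assert np.all((f.rh >= 0) & (f.rh <= 100))
        assert np.all(f.wind >= 0)
        assert np.all(f.rain >= 0)
        assert np.all(f.lightning >= 0)
        assert np.all(f.popdens_field >= 0)

    def test_cover_fractions_sum_below_one(self):
        f = fg.generate_forcing(fg.ScenarioConfig(nlat=4, nlon=4, years=1, seed=2))
        total = f.cover.sum(axis=0)
        assert np.all(total <= 1.0 + 1e-12)
        assert np.all(total > 0.0)

    def test_lightning_climatology_matches_configured_annual_total(self):
        cfg = dataclasses.replace(
            _quiet_cfg(),
            years=40,
            lightning=fg.LightningConfig(
                annual_strikes_km2_yr=1.0,
                noise_sigma=0.5,
                spatial_sigma=0.0,
                annual_sigma=0.0,
                trend_frac_per_century=0.0,
            ),
        )
        f = fg.generate_forcing(cfg)
        annual = f.lightning.sum() / (cfg.years * cfg.ncell)
        assert annual == pytest.approx(1.0, rel=0.1)

    def test_fixed_driver_equals_zero_trend_version(self):
        """Freezing the climate trend at the reference year reproduces the
        zero-trend forcing bit for bit (same streams)."""
        trending = _quiet_cfg(tmax=fg.VariableConfig(0.0, 20.0, 3.5, 0.8, 8.0))
        frozen = fg.generate_forcing(trending, fixed_drivers={"climate"}, ref_year=0)
        no_trend = fg.generate_forcing(
            _quiet_cfg(tmax=fg.VariableConfig(0.0, 20.0, 3.5, 0.8, 0.0))
        )
        np.testing.assert_array_equal(frozen.tmax, no_trend.tmax)

    def test_unknown_driver_rejected(self):
        with pytest.raises(ValueError):
            fg.generate_forcing(_quiet_cfg(), fixed_drivers={"volcanoes"})


class TestDeltaCorrections:
    def test_multiplicative_identity(self, rng):
        series = rng.gamma(1.0, 1.0, (200, 6))
        out = fg.delta_correct_multiplicative(series, series.mean(axis=0))
        np.testing.assert_allclose(out, series, rtol=1e-12)

    def test_multiplicative_halves_doubled_mean(self, rng):
        series = rng.gamma(1.0, 2.0, (500, 4))
        target = series.mean(axis=0) / 2.0
        out = fg.delta_correct_multiplicative(series, target)
        np.testing.assert_allclose(out, series / 2.0, rtol=1e-12)

    def test_multiplicative_conserves_cumulative_total(self, rng):
        """The corrected series carries exactly the target's cumulative
        strike count — the defining conservation property."""
        series = rng.gamma(0.6, 1.5, (365 * 4, 8))
        target = rng.uniform(0.5, 2.0, 8)
        out = fg.delta_correct_multiplicative(series, target)
        np.testing.assert_allclose(
            out.sum(axis=0), target * series.shape[0], rtol=1e-9
        )

    def test_multiplicative_preserves_relative_variability(self, rng):
        series = rng.gamma(1.0, 1.0, (300, 3)) + 0.1
        out = fg.delta_correct_multiplicative(series, 2 * series.mean(axis=0))
        np.testing.assert_allclose(
            out / out.mean(axis=0), series / series.mean(axis=0), rtol=1e-12
        )

    def test_zero_source_climatology_flagged(self):
        series = np.zeros((10, 2))
        series[:, 1] = 1.0
        with pytest.warns(UserWarning, match="zero source climatology"):
            out = fg.delta_correct_multiplicative(series, np.array([1.0, 1.0]))
        np.testing.assert_array_equal(out[:, 0], 0.0)

    def test_additive_identity_and_offset(self, rng):
        series = rng.normal(5.0, 1.0, (100, 3))
        np.testing.assert_allclose(
            fg.delta_correct_additive(series, series.mean(axis=0)), series, rtol=1e-12
        )
        out = fg.delta_correct_additive(series, series.mean(axis=0) + 2.0)
        np.testing.assert_allclose(out, series + 2.0, rtol=1e-12)

    def test_additive_clamp_accounting(self, rng):
        """Clamping adds exactly the clamped mass: corrected mean never
        exceeds target plus clamp mass per step."""
        series = rng.normal(1.0, 1.0, (1000, 2))
        target = np.array([0.2, 0.1])
        offset = target - series.mean(axis=0)
        raw = series + offset
        clamp_mass = np.clip(-raw, 0.0, None).sum(axis=0)
        with pytest.warns(UserWarning, match="clamped"):
            out = fg.delta_correct_additive(series, target)
        np.testing.assert_allclose(
            out.mean(axis=0), target + clamp_mass / series.shape[0], rtol=1e-9
        )


class TestRegrowth:
    def test_at_capacity_without_fire_is_stationary(self):
        params = fg.RegrowthParams(capacity={"leaf": 2.0}, tau_years=10.0)
        pools = fg.step_biomass({"leaf": 2.0}, 0.0, params)
        assert pools["leaf"] == pytest.approx(2.0, rel=1e-12)

    def test_recovery_reaches_63_percent_after_one_efolding_time(self):
        params = fg.RegrowthParams(capacity={"leaf": 1.0}, tau_years=1.0)
        pools = {"leaf": 1.0}
        # total burn, then one e-folding time of daily recovery steps
        for day in range(365):
            pools = fg.step_biomass(pools, 1.0 if day == 0 else 0.0, params)
        assert pools["leaf"] == pytest.approx(1.0 - np.exp(-1.0), rel=1e-3)

    def test_zero_regrowth_rate_freezes_pools(self):
        params = fg.RegrowthParams(capacity={"leaf": 1.0}, tau_years=0.0)
        pools = fg.step_biomass({"leaf": 0.8}, 0.5, params)
        assert pools["leaf"] == pytest.approx(0.4, rel=1e-12)
        assert fg.step_biomass(pools, 0.0, params)["leaf"] == pools["leaf"]

    def test_pools_never_negative(self, rng):
        params = fg.RegrowthParams(capacity={"leaf": 1.0}, tau_years=5.0)
        pools = {"leaf": rng.uniform(0, 2)}
        for _ in range(100):
            pools = fg.step_biomass(pools, rng.uniform(0, 1), params)
            assert pools["leaf"] >= 0.0
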