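"""Synthetic gridded daily forcing and lightning bias correction.

The generator emulates the statistical structure of the meteorological,
lightning and population forcing a boreal fire model is driven with:
seasonal cycles, AR(1)-autocorrelated weather noise, a negative
humidity-temperature coupling, secular trends (warming, drying, lightning
increase, population growth, CO2-driven biomass gain), and spatially
heterogeneous population and vegetation fields.  Every variable draws
from its own named random stream, so adding or removing one variable
never perturbs the others, and the whole forcing is reproducible from a
single seed.

A 365-day (no-leap) calendar is used throughout.

The delta-method bias corrections mirror the standard treatment of
lightning time series: a per-cell multiplicative scaling (which conserves
the cumulative strike count of the target climatology while preserving
relative variability) or an additive offset (clamped at zero for strike
densities).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import lfilter

__all__ = [
    "ALL_DRIVERS",
    "VariableConfig",
    "RainConfig",
    "LightningConfig",
    "PopulationConfig",
    "ScenarioConfig",
    "Forcing",
    "generate_forcing",
    "delta_correct_multiplicative",
    "delta_correct_additive",
    "RegrowthParams",
    "step_biomass",
]

#: The four forcing drivers a factorial experiment can hold fixed.
ALL_DRIVERS = ("climate", "lightning", "co2_biomass", "population")

DAYS_PER_YEAR = 365
_SUMMER_PEAK_DOY = 200

# fixed ids of the named random streams (never renumber)
_STREAMS = {
    "tmax": 1,
    "rh": 2,
    "wind": 3,
    "rain": 4,
    "lightning": 5,
    "popdens": 6,
    "cover": 7,
}


def _stream(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), _STREAMS[name]])


@dataclass(frozen=True)
class VariableConfig:
    """Seasonal-plus-AR(1) model for one meteorological variable.

    ``mean`` and ``amplitude`` define the seasonal cycle
    ``mean + amplitude * cos(2 pi (doy - peak) / 365)`` (a negative
    amplitude puts the minimum in summer).  ``sigma``/``rho`` are the
    stationary standard deviation and lag-1 autocorrelation of the daily
    anomaly.  ``trend_per_century`` is additive in the variable's units.
    """

    mean: float
    amplitude: float
    sigma: float
    rho: float
    trend_per_century: float = 0.0
    #: std dev of a domain-wide (synoptic/continental-scale) AR(1) anomaly
    #: shared by all cells; this is what gives the domain total realistic
    #: interannual variability despite cell-level noise averaging out.
    sigma_domain: float = 0.0
    rho_domain: float = 0.95


@dataclass(frozen=True)
class RainConfig:
    """Daily rainfall: wet days are Bernoulli draws, amounts exponential."""

    p_wet: float = 0.35
    mean_mm: float = 6.0
    trend_frac_per_century: float = 0.0  # multiplicative change of amounts


@dataclass(frozen=True)
class LightningConfig:
    """Cloud-to-ground strike density with a Gaussian summer season.

    ``annual_strikes_km2_yr`` is the climatological cumulative density;
    ``season_width_days`` the Gaussian width around the mid-summer peak;
    ``noise_sigma`` the log-normal day-to-day multiplier spread;
    ``spatial_sigma`` the log-normal spread of the static per-cell
    multiplier; ``trend_frac_per_century`` the fractional increase of the
    whole field per century.
    """

    annual_strikes_km2_yr: float = 1.0
    season_width_days: float = 45.0
    noise_sigma: float = 1.0
    spatial_sigma: float = 0.4
    #: log-normal sigma of a per-year domain-wide activity multiplier
    #: (active vs quiet lightning seasons).
    annual_sigma: float = 0.3
    trend_frac_per_century: float = 0.5


@dataclass(frozen=True)
class PopulationConfig:
    """Static log-normal population density field with an optional trend."""

    median_km2: float = 0.03
    sigma_log: float = 1.5
    trend_frac_per_century: float = 0.0


@dataclass(frozen=True)
class PftParams:
    """One plant functional type: spread behaviour, cover, carbon pools."""

    name: str
    spread_class: str  # needleleaf | broadleaf | grass
    vdmax_kmh: float
    cover: float  # mean fraction of cell area
    capacity: dict  # kg C m^-2 carrying capacity per pool
    tau_live_yr: float  # regrowth e-folding time of live pools
    r_green: float = 0.5  # green fraction of grass leaf biomass


def default_pfts() -> tuple[PftParams, ...]:
    """The default boreal PFT set (maximum spread rates from the Canadian
    fire-behaviour classification: 2.3 / 3.8 / 0.92 / 4.97 km/h)."""
    tree_cap = {"leaf": 0.4, "stem": 5.0, "root": 1.5, "litter": 2.5, "soil": 15.0}
    broad_cap = {"leaf": 0.3, "stem": 4.0, "root": 1.2, "litter": 2.0, "soil": 12.0}
    grass_cap = {"leaf": 0.15, "stem": 0.05, "root": 0.5, "litter": 0.5, "soil": 10.0}
    return (
        PftParams("needleleaf_evergreen", "needleleaf", 2.3, 0.35, tree_cap, 40.0),
        PftParams("needleleaf_continental", "needleleaf", 3.8, 0.10, tree_cap, 40.0),
        PftParams("broadleaf", "broadleaf", 0.92, 0.15, broad_cap, 30.0),
        PftParams("grass", "grass", 4.97, 0.15, grass_cap, 3.0),
    )


@dataclass(frozen=True)
class ScenarioConfig:
    """Everything needed to generate a reproducible synthetic scenario."""

    nlat: int = 20
    nlon: int = 20
    cell_area_km2: float = 576.0  # ~0.22 degree cell in the boreal zone
    years: int = 30
    seed: int = 0
    tmax: VariableConfig = field(
        default_factory=lambda: VariableConfig(0.0, 20.0, 3.5, 0.8, 4.0, sigma_domain=1.5)
    )
    rh: VariableConfig = field(
        default_factory=lambda: VariableConfig(70.0, -12.0, 8.0, 0.7, -5.0, sigma_domain=4.0)
    )
    wind: VariableConfig = field(
        default_factory=lambda: VariableConfig(12.0, 2.0, 5.0, 0.5, 0.0)
    )
    rain: RainConfig = field(default_factory=RainConfig)
    lightning: LightningConfig = field(default_factory=LightningConfig)
    population: PopulationConfig = field(default_factory=PopulationConfig)
    rh_temp_coupling: float = -1.2  # % RH per degC of temperature anomaly
    co2_biomass_trend_frac_per_century: float = 0.2
    pfts: tuple = field(default_factory=default_pfts)

    @property
    def ncell(self) -> int:
        return self.nlat * self.nlon

    def with_seed(self, seed: int) -> "ScenarioConfig":
        return replace(self, seed=seed)


@dataclass
class Forcing:
    """Generated daily forcing on the flattened grid (time, cell)."""

    cfg: ScenarioConfig
    doy: np.ndarray  # (nday,) 1..365
    month: np.ndarray  # (nday,) 1..12
    year_index: np.ndarray  # (nday,) 0-based simulation year
    tmax: np.ndarray  # degC (nday, ncell)
    rh: np.ndarray  # % (nday, ncell)
    wind: np.ndarray  # km/h (nday, ncell)
    rain: np.ndarray  # mm/day (nday, ncell)
    lightning: np.ndarray  # strikes km^-2 day^-1 (nday, ncell)
    popdens_field: np.ndarray  # persons km^-2 (ncell,)
    popdens_mult: np.ndarray  # (nday,) temporal multiplier
    cap_mult: np.ndarray  # (nday,) biomass carrying-capacity multiplier
    cover: np.ndarray  # (npft, ncell) PFT cover fractions

    @property
    def nday(self) -> int:
        return self.tmax.shape[0]

    def popdens(self, d: int) -> np.ndarray:
        return self.popdens_field * self.popdens_mult[d]


_MONTH_EDGES = np.cumsum([0, 31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])


def _calendar(years: int):
    doy = np.tile(np.arange(1, DAYS_PER_YEAR + 1), years)
    month = np.searchsorted(_MONTH_EDGES, doy[:DAYS_PER_YEAR], side="left")
    month = np.tile(month, years)
    year_index = np.repeat(np.arange(years), DAYS_PER_YEAR)
    return doy, month, year_index


def _seasonal(doy, mean, amplitude, peak=_SUMMER_PEAK_DOY):
    return mean + amplitude * np.cos(2.0 * np.pi * (doy - peak) / DAYS_PER_YEAR)


def _ar1(rng, sigma, rho, shape):
    if sigma == 0.0:
        return np.zeros(shape)
    eps = rng.normal(0.0, sigma * np.sqrt(1.0 - rho**2), shape)
    return lfilter([1.0], [1.0, -rho], eps, axis=0)


def _anomaly(rng, var: VariableConfig, nday: int, ncell: int):
    """Cell-level plus domain-wide AR(1) anomalies for one variable."""
    local = _ar1(rng, var.sigma, var.rho, (nday, ncell))
    if var.sigma_domain > 0.0:
        local = local + _ar1(rng, var.sigma_domain, var.rho_domain, (nday, 1))
    return local


def _trend_years(year_frac, driver, fixed, ref_year):
    """Time axis (in years) the trend term sees; frozen for fixed drivers."""
    if driver in fixed:
        return np.full_like(year_frac, float(ref_year))
    return year_frac


def generate_forcing(
    cfg: ScenarioConfig,
    fixed_drivers: frozenset | set = frozenset(),
    ref_year: float = 0.0,
) -> Forcing:
    """Generate the full daily forcing for a scenario.

    ``fixed_drivers`` (any subset of ``ALL_DRIVERS``) freezes the secular
    trend of those drivers at its ``ref_year`` value while leaving the
    seasonal cycle and noise untouched — the factorial-experiment
    construction.  With no trends and no fixing, identical seeds give
    bit-identical output.
    """
    bad = set(fixed_drivers) - set(ALL_DRIVERS)
    if bad:
        raise ValueError(f"unknown drivers in factorial mask: {sorted(bad)}")
    ncell = cfg.ncell
    nday = cfg.years * DAYS_PER_YEAR
    doy, month, year_index = _calendar(cfg.years)
    year_frac = np.arange(nday) / DAYS_PER_YEAR

    t_clim = _trend_years(year_frac, "climate", fixed_drivers, ref_year)

    tmax_anom = _anomaly(_stream(cfg.seed, "tmax"), cfg.tmax, nday, ncell)
    tmax = (
        _seasonal(doy, cfg.tmax.mean, cfg.tmax.amplitude)[:, None]
        + tmax_anom
        + (cfg.tmax.trend_per_century * t_clim / 100.0)[:, None]
    )

    rh_anom = _anomaly(_stream(cfg.seed, "rh"), cfg.rh, nday, ncell)
    rh = (
        _seasonal(doy, cfg.rh.mean, cfg.rh.amplitude)[:, None]
        + rh_anom
        + cfg.rh_temp_coupling * tmax_anom
        + (cfg.rh.trend_per_century * t_clim / 100.0)[:, None]
    )
    rh = np.clip(rh, 0.0, 100.0)

    wind_anom = _anomaly(_stream(cfg.seed, "wind"), cfg.wind, nday, ncell)
    wind = np.maximum(
        _seasonal(doy, cfg.wind.mean, cfg.wind.amplitude)[:, None]
        + wind_anom
        + (cfg.wind.trend_per_century * t_clim / 100.0)[:, None],
        0.0,
    )

    rng_rain = _stream(cfg.seed, "rain")
    wet = rng_rain.random((nday, ncell)) < cfg.rain.p_wet
    amounts = rng_rain.exponential(cfg.rain.mean_mm, (nday, ncell))
    rain_mult = 1.0 + cfg.rain.trend_frac_per_century * t_clim / 100.0
    rain = wet * amounts * rain_mult[:, None]

    rng_ltg = _stream(cfg.seed, "lightning")
    shape = np.exp(-0.5 * ((np.arange(1, DAYS_PER_YEAR + 1) - _SUMMER_PEAK_DOY) / cfg.lightning.season_width_days) ** 2)
    daily_clim = cfg.lightning.annual_strikes_km2_yr * shape / shape.sum()
    daily_clim = np.tile(daily_clim, cfg.years)
    spatial = np.exp(
        rng_ltg.normal(
            -0.5 * cfg.lightning.spatial_sigma**2, cfg.lightning.spatial_sigma, ncell
        )
    )
    noise = np.exp(
        rng_ltg.normal(
            -0.5 * cfg.lightning.noise_sigma**2, cfg.lightning.noise_sigma, (nday, ncell)
        )
    )
    t_ltg = _trend_years(year_frac, "lightning", fixed_drivers, ref_year)
    ltg_mult = np.maximum(1.0 + cfg.lightning.trend_frac_per_century * t_ltg / 100.0, 0.0)
    if cfg.lightning.annual_sigma > 0.0:
        yearly = np.exp(
            rng_ltg.normal(
                -0.5 * cfg.lightning.annual_sigma**2,
                cfg.lightning.annual_sigma,
                cfg.years,
            )
        )
        ltg_mult = ltg_mult * yearly[year_index]
    lightning = daily_clim[:, None] * spatial[None, :] * noise * ltg_mult[:, None]

    rng_pop = _stream(cfg.seed, "popdens")
    popdens_field = cfg.population.median_km2 * np.exp(
        rng_pop.normal(0.0, cfg.population.sigma_log, ncell)
    )
    t_pop = _trend_years(year_frac, "population", fixed_drivers, ref_year)
    popdens_mult = np.maximum(
        1.0 + cfg.population.trend_frac_per_century * t_pop / 100.0, 0.0
    )

    t_co2 = _trend_years(year_frac, "co2_biomass", fixed_drivers, ref_year)
    cap_mult = np.maximum(
        1.0 + cfg.co2_biomass_trend_frac_per_century * t_co2 / 100.0, 0.0
    )

    rng_cov = _stream(cfg.seed, "cover")
    npft = len(cfg.pfts)
    base = np.array([p.cover for p in cfg.pfts])
    weights = base[:, None] * np.exp(rng_cov.normal(0.0, 0.5, (npft, ncell)))
    veg_total = rng_cov.uniform(0.6, 0.95, ncell)
    cover = weights / weights.sum(axis=0, keepdims=True) * veg_total[None, :]

    return Forcing(
        cfg=cfg,
        doy=doy,
        month=month,
        year_index=year_index,
        tmax=tmax,
        rh=rh,
        wind=wind,
        rain=rain,
        lightning=lightning,
        popdens_field=popdens_field,
        popdens_mult=popdens_mult,
        cap_mult=cap_mult,
        cover=cover,
    )


# ---------------------------------------------------------------------------
# delta-method bias correction


def delta_correct_multiplicative(series: np.ndarray, target_climatology) -> np.ndarray:
    """Scale a (time, ...) series per cell so its long-term mean matches the
    target climatology.

    The corrected series has exactly the target's cumulative total while
    the relative (intra-series) variability is untouched.  Cells whose
    source climatology is zero but whose target is nonzero cannot be
    corrected multiplicatively; they are left unchanged and a warning is
    issued.
    """
    series = np.asarray(series, dtype=float)
    target = np.broadcast_to(np.asarray(target_climatology, dtype=float), series.shape[1:])
    src_mean = series.mean(axis=0)
    ok = src_mean > 0.0
    flagged = (~ok) & (target > 0.0)
    if np.any(flagged):
        warnings.warn(
            f"{int(flagged.sum())} cell(s) have zero source climatology with a "
            "nonzero target; left uncorrected",
            stacklevel=2,
        )
    factor = np.where(ok, target / np.where(ok, src_mean, 1.0), 1.0)
    return series * factor


def delta_correct_additive(
    series: np.ndarray, target_climatology, clamp_nonnegative: bool = True
) -> np.ndarray:
    """Offset a (time, ...) series per cell so its mean matches the target.

    For strike densities, negative corrected values are clamped at zero
    (with a warning); clamping adds mass, so the corrected mean can
    exceed the target by exactly the clamped amount per step.
    """
    series = np.asarray(series, dtype=float)
    target = np.broadcast_to(np.asarray(target_climatology, dtype=float), series.shape[1:])
    offset = target - series.mean(axis=0)
    corrected = series + offset
    if clamp_nonnegative and np.any(corrected < 0.0):
        warnings.warn(
            "additive delta correction produced negative values; clamped at 0",
            stacklevel=2,
        )
        corrected = np.maximum(corrected, 0.0)
    return corrected


# ---------------------------------------------------------------------------
# fuel regrowth


@dataclass(frozen=True)
class RegrowthParams:
    """Exponential relaxation of carbon pools toward carrying capacity.

    ``capacity`` maps pool name to kg C m^-2; ``tau_years`` is the
    e-folding recovery time; ``dt_days`` the step length.  ``tau_years``
    of 0 disables regrowth (pools stay where the fire left them).
    """

    capacity: dict
    tau_years: float
    dt_days: float = 1.0


def step_biomass(pools: dict, burned_fraction, params: RegrowthParams) -> dict:
    """Remove the burned fraction of every pool, then relax toward capacity.

    A closed-form step of dC/dt = (K - C)/tau: after one e-folding time a
    fully burned pool recovers to (1 - 1/e) of capacity.  Pools never go
    negative.
    """
    bf = np.asarray(burned_fraction, dtype=float)
    if np.any(bf < 0.0) or np.any(bf > 1.0):
        raise ValueError("burned_fraction out of [0, 1]")
    if params.tau_years > 0.0:
        decay = 1.0 - np.exp(-params.dt_days / (params.tau_years * 365.0))
    else:
        decay = 0.0
    out = {}
    for pool, dens in pools.items():
        dens = np.asarray(dens, dtype=float) * (1.0 - bf)
        cap = params.capacity.get(pool, 0.0)
        dens = dens + (cap - dens) * decay
        dens = np.maximum(dens, 0.0)
        out[pool] = float(dens) if dens.ndim == 0 else dens
    return out
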