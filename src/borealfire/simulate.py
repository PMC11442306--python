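"""Daily-timestep fire simulation over a gridded scenario.

Chains the component models — fire-weather codes (FWI), occurrence
probability, per-PFT elliptical spread and burned area, carbon fluxes,
fuel regrowth — for every cell and day of a scenario.  A spin-up phase
with all secular trends frozen at the reference year lets the moisture
codes and the fire/regrowth balance of the carbon pools equilibrate
before the transient period is recorded.  Domain annual totals are
area-weighted sums over cells.

The inner day loop uses a batched kernel with all PFT parameters packed
into arrays; it computes exactly the same chain as the public functions
in :mod:`borealfire.occurrence`, :mod:`borealfire.spread` and
:mod:`borealfire.carbon` (the test suite asserts the equivalence), just
without per-call validation, because the loop runs tens of thousands of
times.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from . import fwi
from .carbon import ALL_POOLS, C_TO_CO2, LIVE_POOLS, CombustionParams
from .forcing import (
    ALL_DRIVERS,
    Forcing,
    ScenarioConfig,
    generate_forcing,
)
from .occurrence import DAYS_PER_YEAR as ANNUALIZE_DAYS
from .occurrence import OccurrenceParams
from .spread import SpreadParams

__all__ = ["RunProtocol", "ModelParams", "RunResult", "run_simulation"]

KM2_PER_MHA = 1.0e4
TAU_LITTER_YR = 20.0
TAU_SOIL_YR = 100.0

_POOL_INDEX = {p: i for i, p in enumerate(ALL_POOLS)}
_LEAF, _STEM, _ROOT, _LITTER, _SOIL = (_POOL_INDEX[p] for p in ALL_POOLS)


def load_default_combustion() -> dict:
    """Per-PFT combustion parameter tables from the bundled YAML."""
    text = resources.files("borealfire.data").joinpath("combustion.yaml").read_text()
    raw = yaml.safe_load(text)
    return {
        name: CombustionParams(
            emission_frac=entry["emission_frac"],
            mortality_frac=entry["mortality_frac"],
        )
        for name, entry in raw.items()
    }


@dataclass(frozen=True)
class RunProtocol:
    """Spin-up length, transient length and the factorial driver mask.

    The default 60-year spin-up is about 1.5 e-folding times of the
    slowest live pool, enough to bring the fire/regrowth balance close to
    equilibrium under reference forcing.
    """

    years: int = 30
    spinup_years: int = 60
    fixed_drivers: frozenset = frozenset()
    ref_year: float = 0.0

    def __post_init__(self) -> None:
        bad = set(self.fixed_drivers) - set(ALL_DRIVERS)
        if bad:
            raise ValueError(f"unknown drivers in factorial mask: {sorted(bad)}")


@dataclass(frozen=True)
class ModelParams:
    """All fire-module parameters in one place."""

    occurrence: OccurrenceParams = field(default_factory=OccurrenceParams)
    spread: SpreadParams = field(default_factory=SpreadParams)
    combustion: dict = field(default_factory=load_default_combustion)


@dataclass
class RunResult:
    """Annual diagnostics of one simulation."""

    year: np.ndarray  # (nyear,)
    burned_km2: np.ndarray  # (nyear,) domain total
    co2_kg: np.ndarray  # (nyear,) domain total
    burned_map_km2: np.ndarray  # (nyear, ncell)
    co2_map_kg: np.ndarray  # (nyear, ncell)
    driver_means: pd.DataFrame  # annual domain-mean drivers
    scenario: ScenarioConfig
    protocol: RunProtocol

    @property
    def burned_mha(self) -> np.ndarray:
        return self.burned_km2 / KM2_PER_MHA

    @property
    def co2_pg(self) -> np.ndarray:
        return self.co2_kg * 1.0e-12

    def annual_table(self) -> pd.DataFrame:
        df = self.driver_means.copy()
        df["burned_km2"] = self.burned_km2
        df["burned_mha"] = self.burned_mha
        df["co2_kg"] = self.co2_kg
        df["co2_pg"] = self.co2_pg
        return df


class _Kernel:
    """PFT-batched parameter pack and state for the daily loop."""

    def __init__(self, scenario: ScenarioConfig, params: ModelParams):
        pfts = scenario.pfts
        npft, npool, ncell = len(pfts), len(ALL_POOLS), scenario.ncell
        sp = params.spread

        self.grass = np.array([p.spread_class == "grass" for p in pfts])[:, None]
        self.vdmax = np.array(
            [sp.vdmax_kmh.get(p.name, p.vdmax_kmh) for p in pfts]
        )[:, None]
        self.r_green = np.array([p.r_green for p in pfts])[:, None]
        # tree ISI/BUI curve constants; grass rows get needleleaf values but
        # are masked out of the tree branch
        from .spread import _BUI_CURVE, _ISI_CURVE  # curve tables

        def tree(p, table, j, default):
            return table.get(p.spread_class, default)[j]

        self.isi_c = np.array(
            [tree(p, _ISI_CURVE, 0, (0.0232, 1.6)) for p in pfts]
        )[:, None]
        self.isi_p = np.array(
            [tree(p, _ISI_CURVE, 1, (0.0232, 1.6)) for p in pfts]
        )[:, None]
        self.bui_scale = np.array(
            [tree(p, _BUI_CURVE, 0, (0.7568, 17.8337, 64.0)) for p in pfts]
        )[:, None]
        self.bui_rate = np.array(
            [tree(p, _BUI_CURVE, 1, (0.7568, 17.8337, 64.0)) for p in pfts]
        )[:, None]
        self.bui_refinv = 1.0 / np.array(
            [tree(p, _BUI_CURVE, 2, (0.7568, 17.8337, 64.0)) for p in pfts]
        )[:, None]

        emis = np.zeros((npft, npool, 1))
        mort = np.zeros((npft, npool, 1))
        for i, p in enumerate(pfts):
            comb = params.combustion.get(p.name, CombustionParams())
            for pool, j in _POOL_INDEX.items():
                emis[i, j, 0] = comb.emission_frac.get(pool, 0.0)
                if pool in LIVE_POOLS:
                    mort[i, j, 0] = comb.mortality_frac.get(pool, 0.0)
        self.emis, self.mort = emis, mort

        tau = np.empty((npft, npool, 1))
        for i, p in enumerate(pfts):
            for pool, j in _POOL_INDEX.items():
                tau[i, j, 0] = (
                    p.tau_live_yr
                    if pool in LIVE_POOLS
                    else (TAU_LITTER_YR if pool == "litter" else TAU_SOIL_YR)
                )
        self.decay = 1.0 - np.exp(-1.0 / (365.0 * tau))
        self.cap = np.zeros((npft, npool, 1))
        for i, p in enumerate(pfts):
            for pool, j in _POOL_INDEX.items():
                self.cap[i, j, 0] = p.capacity.get(pool, 0.0)
        self.live_mask = np.array(
            [[pool in LIVE_POOLS] for pool in ALL_POOLS]
        ).reshape(1, npool, 1)

        self.ffmc = np.full(ncell, fwi.FFMC_START)
        self.dmc = np.full(ncell, fwi.DMC_START)
        self.dc = np.full(ncell, fwi.DC_START)
        self.pools = np.broadcast_to(self.cap, (npft, npool, ncell)).copy()
        self.occ = params.occurrence
        self.sp = sp


def _simulate_days(forcing: Forcing, k: _Kernel, record: bool):
    """Advance the kernel state over every day of `forcing`."""
    cfg = forcing.cfg
    ncell = cfg.ncell
    ag = cfg.cell_area_km2
    occ, sp = k.occ, k.sp
    cover = forcing.cover  # (npft, ncell)
    extent = ag * cover
    ext_safe = np.maximum(extent, 1e-300)
    v_sum_factor = (1.0 + sp.vu_fraction) * sp.fire_day_hours
    qv = np.log(-np.log(1.0 - np.exp(-np.pi)) / np.pi) / np.log(sp.pd_min / sp.pd_max)

    for name in ("tmax", "rh", "wind", "rain", "lightning"):
        arr = getattr(forcing, name)
        if not np.all(np.isfinite(arr)):
            day, cell = np.argwhere(~np.isfinite(arr))[0]
            raise FloatingPointError(
                f"non-finite {name} forcing at day {day}, cell {cell}"
            )

    if record:
        years = cfg.years
        burned_map = np.zeros((years, ncell))
        co2_map = np.zeros((years, ncell))
        vegc_sum = np.zeros(years)

    pop_mult_cached = None
    for d in range(forcing.nday):
        wind = forcing.wind[d]
        k.ffmc, k.dmc, k.dc, isi, bui = fwi.step_fwi_arrays(
            k.ffmc, k.dmc, k.dc,
            forcing.tmax[d], forcing.rh[d], wind, forcing.rain[d],
            int(forcing.month[d]), validate=False,
        )

        pools = k.pools
        agb = (cover * (pools[:, _LEAF] + pools[:, _STEM])).sum(axis=0)
        p_b = np.clip(
            (agb - occ.biomass_lo) / (occ.biomass_hi - occ.biomass_lo), 0.0, 1.0
        )
        p_m = 1.0 / (1.0 + np.exp(-(occ.pm_intercept + occ.pm_slope * k.ffmc)))
        ltg_yr = forcing.lightning[d] * ANNUALIZE_DAYS
        p_nat = np.clip(
            (ltg_yr - occ.lightning_lo) / (occ.lightning_hi - occ.lightning_lo),
            0.0,
            1.0,
        )
        # population enters only through slowly varying q and p_hum;
        # recompute only when the temporal multiplier changes
        if forcing.popdens_mult[d] != pop_mult_cached:
            pop_mult_cached = forcing.popdens_mult[d]
            popdens = forcing.popdens_field * pop_mult_cached
            p_hum = np.minimum(1.0, (popdens / occ.popdens_sat) ** occ.human_exponent)
            q = np.clip(
                0.5 + 0.5 * (1.0 - np.exp(-np.pi * (popdens / sp.pd_max) ** qv)),
                0.5,
                np.nextafter(1.0, 0.0),
            )
            duration_mult = (1.0 - q) * (2.0 - q) / q**2
        p_f = p_b * (p_nat + (1.0 - p_nat) * p_hum) * p_m

        lb = 1.0 + sp.lb_scale * (1.0 - np.exp(-sp.lb_rate * wind))

        fisi_tree = (1.0 - np.exp(-k.isi_c * isi)) ** k.isi_p
        bui_safe = np.maximum(bui, 1e-300)
        gbui = np.where(
            bui > 0.0,
            k.bui_scale * np.exp(-k.bui_rate * (1.0 / bui_safe - k.bui_refinv)),
            0.0,
        )
        v_tree = k.vdmax * fisi_tree * gbui
        v_grass = k.vdmax * k.r_green * (1.0 - np.exp(-0.031 * isi)) ** 1.4 + (
            1.3 * k.vdmax
        ) * (1.0 - k.r_green) * (1.0 - np.exp(-0.035 * isi)) ** 1.7
        v_d = np.where(k.grass, v_grass, v_tree)  # (npft, ncell)

        length = v_d * v_sum_factor
        a1 = (np.pi / 4.0) * length * length / lb
        ar = a1 * duration_mult
        ab = np.minimum(p_f * ar * extent / sp.a_rep_km2, extent)
        bf = np.where(extent > 0.0, ab / ext_safe, 0.0)[:, None, :]

        removed = pools * bf * (k.emis + k.mort)
        killed = (pools * bf * k.mort).sum(axis=1)
        if record:
            y = int(forcing.year_index[d])
            co2_cell = ((pools * bf * k.emis).sum(axis=1) * extent).sum(axis=0)
            co2_map[y] += co2_cell * 1.0e6 * C_TO_CO2
            burned_map[y] += ab.sum(axis=0)
        pools -= removed
        pools[:, _LITTER] += killed
        cap = k.cap * np.where(k.live_mask, float(forcing.cap_mult[d]), 1.0)
        pools += (cap - pools) * k.decay
        np.maximum(pools, 0.0, out=pools)

        if record:
            vegc = (
                cover * (pools[:, _LEAF] + pools[:, _STEM] + pools[:, _ROOT])
            ).sum(axis=0)
            vegc_sum[y] += vegc.mean()

    if not record:
        return None
    return burned_map, co2_map, vegc_sum / 365.0


def run_simulation(
    protocol: RunProtocol,
    scenario: ScenarioConfig,
    params: ModelParams | None = None,
) -> RunResult:
    """Spin up, then run the transient scenario; return annual diagnostics.

    Deterministic: identical protocol + scenario (including seed) give
    bit-identical annual totals.
    """
    if params is None:
        params = ModelParams()
    kernel = _Kernel(scenario, params)

    transient = generate_forcing(
        dataclasses.replace(scenario, years=protocol.years),
        fixed_drivers=frozenset(protocol.fixed_drivers),
        ref_year=protocol.ref_year,
    )
    if protocol.spinup_years > 0:
        spin_cfg = dataclasses.replace(scenario, years=protocol.spinup_years)
        spin = generate_forcing(
            spin_cfg, fixed_drivers=frozenset(ALL_DRIVERS), ref_year=protocol.ref_year
        )
        # spin-up reuses the transient cover so the landscape is consistent
        spin.cover = transient.cover
        _simulate_days(spin, kernel, record=False)

    burned_map, co2_map, vegc = _simulate_days(transient, kernel, record=True)

    nyear = protocol.years
    year = np.arange(nyear)
    day_year = transient.year_index
    driver_means = pd.DataFrame(
        {
            "year": year,
            "tmax_c": [transient.tmax[day_year == y].mean() for y in year],
            "rh_pct": [transient.rh[day_year == y].mean() for y in year],
            "wind_kmh": [transient.wind[day_year == y].mean() for y in year],
            "rain_mm": [transient.rain[day_year == y].mean() for y in year],
            "lightning_km2_yr": [
                transient.lightning[day_year == y].mean(axis=0).mean() * 365.0
                for y in year
            ],
            "popdens_km2": [
                transient.popdens_field.mean()
                * transient.popdens_mult[day_year == y].mean()
                for y in year
            ],
            "vegc_kgC_m2": vegc,
        }
    )
    return RunResult(
        year=year,
        burned_km2=burned_map.sum(axis=1),
        co2_kg=co2_map.sum(axis=1),
        burned_map_km2=burned_map,
        co2_map_kg=co2_map,
        driver_means=driver_means,
        scenario=scenario,
        protocol=protocol,
    )
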