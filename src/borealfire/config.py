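"""One-file YAML configuration for scenarios, parameters and protocols.

The configuration has up to six sections — ``grid``, ``occurrence``,
``spread``, ``combustion``, ``scenario`` and ``experiment`` — all
optional; anything omitted falls back to the package defaults.  Example::

    grid:       {nlat: 10, nlon: 10, cell_area_km2: 576}
    occurrence: {lightning_hi: 10.0, popdens_sat: 300.0}
    spread:     {a_rep_km2: 800.0, pd_min: 0.001, pd_max: 0.1}
    combustion:
      grass: {emission_frac: {leaf: 0.9}}
    scenario:
      seed: 7
      years: 30
      tmax: {mean: 0.0, amplitude: 20.0, sigma: 3.5, rho: 0.8,
             trend_per_century: 4.0}
      lightning: {annual_strikes_km2_yr: 1.0, trend_frac_per_century: 0.5}
    experiment: {years: 30, spinup_years: 60}
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .carbon import CombustionParams
from .forcing import (
    LightningConfig,
    PopulationConfig,
    RainConfig,
    ScenarioConfig,
    VariableConfig,
)
from .occurrence import OccurrenceParams
from .simulate import ModelParams, RunProtocol, load_default_combustion
from .spread import SpreadParams

__all__ = ["load_config", "scenario_from_dict", "params_from_dict", "protocol_from_dict"]


def _update(dc_obj, overrides: dict):
    unknown = set(overrides) - {f.name for f in dataclasses.fields(dc_obj)}
    if unknown:
        raise KeyError(
            f"unknown option(s) {sorted(unknown)} for {type(dc_obj).__name__}"
        )
    return dataclasses.replace(dc_obj, **overrides)


def scenario_from_dict(raw: dict) -> ScenarioConfig:
    raw = dict(raw or {})
    cfg = ScenarioConfig()
    nested = {
        "tmax": VariableConfig,
        "rh": VariableConfig,
        "wind": VariableConfig,
        "rain": RainConfig,
        "lightning": LightningConfig,
        "population": PopulationConfig,
    }
    overrides = {}
    for key, cls in nested.items():
        if key in raw:
            overrides[key] = _update(getattr(cfg, key), raw.pop(key))
    overrides.update(raw)
    return _update(cfg, overrides)


def params_from_dict(
    occurrence: dict | None = None,
    spread: dict | None = None,
    combustion: dict | None = None,
) -> ModelParams:
    occ = _update(OccurrenceParams(), occurrence or {})
    sp = _update(SpreadParams(), spread or {})
    comb = load_default_combustion()
    for pft, entry in (combustion or {}).items():
        base = comb.get(pft, CombustionParams())
        comb[pft] = CombustionParams(
            emission_frac={**base.emission_frac, **entry.get("emission_frac", {})},
            mortality_frac={**base.mortality_frac, **entry.get("mortality_frac", {})},
        )
    return ModelParams(occurrence=occ, spread=sp, combustion=comb)


def protocol_from_dict(raw: dict | None) -> RunProtocol:
    raw = dict(raw or {})
    if "fixed_drivers" in raw:
        raw["fixed_drivers"] = frozenset(raw["fixed_drivers"])
    return _update(RunProtocol(), raw)


def load_config(path) -> tuple[ScenarioConfig, ModelParams, RunProtocol]:
    """Read a YAML config file into (scenario, params, protocol)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    scen_raw = dict(raw.get("scenario", {}))
    scen_raw.update(raw.get("grid", {}))
    scenario = scenario_from_dict(scen_raw)
    params = params_from_dict(
        raw.get("occurrence"), raw.get("spread"), raw.get("combustion")
    )
    protocol = protocol_from_dict(raw.get("experiment"))
    return scenario, params, protocol
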