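"""Fire carbon accounting: combustion emissions and fire-kill mortality.

For each plant functional type, the burned fraction of its extent is
applied to its carbon pools.  Each pool loses ``pool * burned_fraction *
emission_frac`` to the atmosphere as CO2 (mass conversion 44/12); the
live pools (leaf, stem, root) additionally transfer ``pool *
burned_fraction * mortality_frac`` of fire-killed but uncombusted carbon
to the litter pool.  Litter and soil carry only an emission fraction.
Soil combustion is a single bulk fraction standing for the depth
distribution and average combustibility of the soil profile.

The per-PFT emission and mortality fraction tables are model parameters
(see ``data/combustion.yaml``); the values shipped here are synthetic
placeholders ordered litter > leaf > soil > stem ~ root and are meant to
be overridden from configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LIVE_POOLS",
    "ALL_POOLS",
    "C_TO_CO2",
    "CombustionParams",
    "FireFluxes",
    "apply_fire",
    "emission_intensity",
]

LIVE_POOLS = ("leaf", "stem", "root")
ALL_POOLS = ("leaf", "stem", "root", "litter", "soil")

#: kg CO2 per kg C (molar mass ratio 44/12).
C_TO_CO2 = 44.0 / 12.0

# Synthetic placeholder fractions (no published per-PFT table is bundled);
# combustion ordered litter > leaf > soil > stem ~ root.
_DEFAULT_EMISSION = {
    "leaf": 0.65,
    "stem": 0.20,
    "root": 0.18,
    "litter": 0.80,
    "soil": 0.25,
}
_DEFAULT_MORTALITY = {"leaf": 0.25, "stem": 0.35, "root": 0.25}


@dataclass(frozen=True)
class CombustionParams:
    """Per-pool fire emission fractions and per-live-pool mortality fractions.

    For every live pool the combusted plus killed fractions must not
    exceed one.
    """

    emission_frac: dict = field(default_factory=lambda: dict(_DEFAULT_EMISSION))
    mortality_frac: dict = field(default_factory=lambda: dict(_DEFAULT_MORTALITY))

    def __post_init__(self) -> None:
        for pool in ALL_POOLS:
            e = self.emission_frac.get(pool, 0.0)
            if not (0.0 <= e <= 1.0):
                raise ValueError(f"emission_frac[{pool}] out of [0, 1]: {e}")
        for pool in LIVE_POOLS:
            m = self.mortality_frac.get(pool, 0.0)
            if not (0.0 <= m <= 1.0):
                raise ValueError(f"mortality_frac[{pool}] out of [0, 1]: {m}")
            if self.emission_frac.get(pool, 0.0) + m > 1.0 + 1e-12:
                raise ValueError(
                    f"emission + mortality fractions exceed 1 for live pool {pool}"
                )


@dataclass(frozen=True)
class FireFluxes:
    """Outcome of one fire event on one PFT's pools.

    ``co2_emitted`` maps pool name to kg CO2 emitted per m^2 of PFT
    extent (multiply by burned PFT area in m^2 for mass); ``litter_transfer``
    is the fire-killed carbon moved live -> litter (kg C m^-2).
    """

    co2_emitted: dict
    litter_transfer: float

    @property
    def total_co2(self):
        total = sum(self.co2_emitted.values())
        return float(total) if np.ndim(total) == 0 else total

    @property
    def total_emitted_c(self):
        return self.total_co2 / C_TO_CO2


def apply_fire(pools: dict, burned_fraction, params: CombustionParams | None = None):
    """Apply one fire event to a PFT's carbon pools.

    Parameters
    ----------
    pools : dict
        Carbon density per pool (kg C m^-2), keys from ``ALL_POOLS``.
        Values may be scalars or arrays (vectorised over cells).
    burned_fraction : float or array
        Fraction of the PFT's extent burned, in [0, 1].
    params : CombustionParams, optional
        Emission/mortality fraction tables (defaults are placeholders).

    Returns
    -------
    (FireFluxes, dict)
        The fluxes and the post-fire pools.  Carbon is conserved: the
        pool decrease equals emitted carbon plus the litter transfer
        (which reappears in the returned litter pool).
    """
    if params is None:
        params = CombustionParams()
    bf = np.asarray(burned_fraction, dtype=float)
    if np.any(bf < 0.0) or np.any(bf > 1.0):
        raise ValueError("burned_fraction out of [0, 1]")
    for pool, dens in pools.items():
        if np.any(np.asarray(dens, dtype=float) < 0.0):
            raise ValueError(f"negative carbon density in pool {pool!r}")

    new_pools = {}
    co2 = {}
    litter_gain = 0.0
    for pool in ALL_POOLS:
        if pool not in pools:
            continue
        dens = np.asarray(pools[pool], dtype=float)
        emitted_c = dens * bf * params.emission_frac.get(pool, 0.0)
        killed_c = (
            dens * bf * params.mortality_frac.get(pool, 0.0)
            if pool in LIVE_POOLS
            else 0.0
        )
        co2[pool] = emitted_c * C_TO_CO2
        litter_gain = litter_gain + killed_c
        new_pools[pool] = dens - emitted_c - killed_c
    if "litter" in new_pools:
        new_pools["litter"] = new_pools["litter"] + litter_gain
    # squeeze 0-d arrays back to floats for scalar input
    for pool, dens in new_pools.items():
        if np.ndim(dens) == 0:
            new_pools[pool] = float(dens)
    co2 = {k: (float(v) if np.ndim(v) == 0 else v) for k, v in co2.items()}
    lt = litter_gain if np.ndim(litter_gain) else float(litter_gain)
    return FireFluxes(co2_emitted=co2, litter_transfer=lt), new_pools


def emission_intensity(total_co2_kg, total_burned_m2):
    """Fire emission intensity, kg CO2 per m^2 of burned area.

    Returns NaN where the burned area is zero (undefined ratio).
    """
    co2 = np.asarray(total_co2_kg, dtype=float)
    area = np.asarray(total_burned_m2, dtype=float)
    if np.any(area < 0.0) or np.any(co2 < 0.0):
        raise ValueError("arguments must be >= 0")
    out = np.where(area > 0.0, co2 / np.where(area > 0.0, area, 1.0), np.nan)
    return float(out) if out.ndim == 0 else out
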