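"""Daily fire-occurrence probability.

The probability of fire in a representative area is the product of three
conditional probabilities,

    P_f = P_b * P_i * P_m,

where P_b conditions on aboveground biomass (fuel availability), P_i on
the presence of an ignition source (lightning and people), and P_m on
fine-fuel moisture via the FFMC.  The module is deterministic: P_f enters
the burned-area calculation as an expected value, never as a random draw.

All functions are vectorised over grid cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "OccurrenceParams",
    "prob_biomass",
    "prob_moisture",
    "prob_ignition",
    "prob_fire",
]

#: Days per year used to annualise daily strike densities before the
#: yr^-1 thresholds are applied.
DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class OccurrenceParams:
    """Thresholds and shapes of the three conditional probabilities.

    Attributes
    ----------
    biomass_lo, biomass_hi : float
        Aboveground biomass (kg C m^-2) below/above which P_b is 0/1;
        linear in between.
    lightning_lo, lightning_hi : float
        Cloud-to-ground strike rates (strikes km^-2 yr^-1) bounding the
        linear ramp of the natural-ignition probability.
    popdens_sat : float
        Population density (persons km^-2) at which the human-ignition
        probability reaches one.
    human_exponent : float
        Exponent of the human-ignition power law
        ``min(1, (popdens / popdens_sat) ** human_exponent)``.
    pm_intercept, pm_slope : float
        Coefficients of the logistic moisture probability
        ``sigmoid(pm_intercept + pm_slope * ffmc)``.
    """

    biomass_lo: float = 0.2
    biomass_hi: float = 1.0
    lightning_lo: float = 0.25
    lightning_hi: float = 10.0
    popdens_sat: float = 300.0
    human_exponent: float = 0.43
    pm_intercept: float = -25.2
    pm_slope: float = 0.34


DEFAULT = OccurrenceParams()


def _ramp(x, lo, hi):
    return np.clip((np.asarray(x, dtype=float) - lo) / (hi - lo), 0.0, 1.0)


def prob_biomass(agb_kgC_m2, params: OccurrenceParams = DEFAULT):
    """P_b: piecewise-linear in aboveground biomass (kg C m^-2).

    Exactly 0 at or below ``biomass_lo`` (default 0.2) and exactly 1 at or
    above ``biomass_hi`` (default 1.0).
    """
    agb = np.asarray(agb_kgC_m2, dtype=float)
    if np.any(agb < 0.0):
        raise ValueError("aboveground biomass must be >= 0")
    out = _ramp(agb, params.biomass_lo, params.biomass_hi)
    return float(out) if out.ndim == 0 else out


def prob_moisture(ffmc, params: OccurrenceParams = DEFAULT):
    """P_m: logistic function of the FFMC.

    With the default coefficients, P_m = sigmoid(-25.2 + 0.34 FFMC):
    essentially 0 for moist fine fuel and saturating at 1 once the litter
    layer is very dry (FFMC in the high 80s).
    """
    ffmc = np.asarray(ffmc, dtype=float)
    if np.any(ffmc < 0.0) or np.any(ffmc > 101.0):
        raise ValueError("ffmc out of [0, 101]")
    z = params.pm_intercept + params.pm_slope * ffmc
    out = 1.0 / (1.0 + np.exp(-z))
    return float(out) if out.ndim == 0 else out


def prob_ignition(
    lightning_strikes_km2_yr,
    popdens_km2,
    params: OccurrenceParams = DEFAULT,
):
    """P_i: combined natural (lightning) and human ignition probability.

    The natural component ramps linearly from 0 at ``lightning_lo`` to 1
    at ``lightning_hi`` strikes km^-2 yr^-1.  The human component is a
    saturating power law of population density reaching 1 at
    ``popdens_sat``.  The two are combined complementarily,
    ``p_i = p_nat + (1 - p_nat) * p_hum``, so either source alone can
    saturate ignition.
    """
    ltg = np.asarray(lightning_strikes_km2_yr, dtype=float)
    pop = np.asarray(popdens_km2, dtype=float)
    if np.any(ltg < 0.0) or np.any(pop < 0.0):
        raise ValueError("lightning and population density must be >= 0")
    p_nat = _ramp(ltg, params.lightning_lo, params.lightning_hi)
    p_hum = np.minimum(1.0, (pop / params.popdens_sat) ** params.human_exponent)
    out = p_nat + (1.0 - p_nat) * p_hum
    return float(out) if out.ndim == 0 else out


def prob_fire(p_b, p_i, p_m):
    """P_f = P_b * P_i * P_m, the daily fire-occurrence probability."""
    p_b = np.asarray(p_b, dtype=float)
    p_i = np.asarray(p_i, dtype=float)
    p_m = np.asarray(p_m, dtype=float)
    for name, p in (("p_b", p_b), ("p_i", p_i), ("p_m", p_m)):
        if np.any(p < 0.0) or np.any(p > 1.0):
            raise ValueError(f"{name} out of [0, 1]")
    out = p_b * p_i * p_m
    return float(out) if out.ndim == 0 else out


def annualize_lightning(daily_strikes_km2, days_per_year: float = DAYS_PER_YEAR):
    """Convert a daily strike density to the annualised rate the thresholds use."""
    return np.asarray(daily_strikes_km2, dtype=float) * days_per_year
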