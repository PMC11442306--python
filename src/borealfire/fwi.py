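"""Canadian Forest Fire Weather Index (FWI) system: daily moisture codes and indices.

Implements the daily bookkeeping of the three fuel-moisture codes —

* **FFMC** (Fine Fuel Moisture Code): moisture of the surface needle-litter
  layer, a kinetic drying/wetting model with a one-day time lag.  Higher
  FFMC means drier, more ignitable fine fuel (standard convention).
* **DMC** (Duff Moisture Code): moisture of the loosely compacted organic
  layer of moderate depth.
* **DC** (Drought Code): moisture of the deep, compact organic layer.

and of the two derived fire-behaviour indices —

* **ISI** (Initial Spread Index): combines FFMC and wind speed into a
  spread-rate proxy.
* **BUI** (Buildup Index): combines DMC and DC into a fuel-availability
  proxy.

The equation set is the standard Canadian FWI system formulation
(Van Wagner & Pickett lineage), driven here with daily *maximum* air
temperature rather than noon temperature.  All functions are vectorised:
scalars in, scalar out; arrays in, arrays out (broadcasting applies).

The composite FWI index itself, hourly FFMC, and the overwintering DC
adjustment are deliberately not implemented: the fire module consumes
only FFMC, ISI and BUI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MeteoDay",
    "FwiState",
    "FwiIndices",
    "FFMC_START",
    "DMC_START",
    "DC_START",
    "update_ffmc",
    "update_dmc",
    "update_dc",
    "compute_isi",
    "compute_bui",
    "step_fwi",
]

# Conventional start-up code values after snowmelt.
FFMC_START = 85.0
DMC_START = 6.0
DC_START = 15.0

# Monthly day-length factors for the DMC drying rate (Canadian standard
# table, single latitude band) and day-length adjustment for the DC.
DMC_DAY_LENGTH = np.array(
    [6.5, 7.5, 9.0, 12.8, 13.9, 13.9, 12.4, 10.9, 9.4, 8.0, 7.0, 6.0]
)
DC_DAY_LENGTH = np.array(
    [-1.6, -1.6, -1.6, 0.9, 3.8, 5.8, 6.4, 5.0, 2.4, 0.4, -1.6, -1.6]
)


@dataclass(frozen=True)
class MeteoDay:
    """One cell-day of fire weather.

    Parameters
    ----------
    tmax_c : float
        Daily maximum air temperature, °C.
    rh_pct : float
        Relative humidity, percent in [0, 100].
    wind_kmh : float
        Wind speed, km/h, non-negative.
    rain_mm : float
        Total rainfall, mm/day, non-negative.
    """

    tmax_c: float
    rh_pct: float
    wind_kmh: float
    rain_mm: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.rh_pct <= 100.0):
            raise ValueError(f"rh_pct must be in [0, 100], got {self.rh_pct}")
        if self.wind_kmh < 0.0:
            raise ValueError(f"wind_kmh must be >= 0, got {self.wind_kmh}")
        if self.rain_mm < 0.0:
            raise ValueError(f"rain_mm must be >= 0, got {self.rain_mm}")


@dataclass(frozen=True)
class FwiState:
    """Prognostic moisture codes carried from one day to the next."""

    ffmc: float = FFMC_START
    dmc: float = DMC_START
    dc: float = DC_START

    def __post_init__(self) -> None:
        if not (0.0 <= self.ffmc <= 101.0):
            raise ValueError(f"ffmc must be in [0, 101], got {self.ffmc}")
        if self.dmc < 0.0:
            raise ValueError(f"dmc must be >= 0, got {self.dmc}")
        if self.dc < 0.0:
            raise ValueError(f"dc must be >= 0, got {self.dc}")


@dataclass(frozen=True)
class FwiIndices:
    """Diagnostic indices derived from the updated moisture codes."""

    isi: float
    bui: float


def _validate_met(tmax_c, rh_pct, wind_kmh, rain_mm) -> None:
    rh = np.asarray(rh_pct, dtype=float)
    if np.any(rh < 0.0) or np.any(rh > 100.0):
        raise ValueError("rh_pct out of [0, 100]")
    if np.any(np.asarray(wind_kmh, dtype=float) < 0.0):
        raise ValueError("wind_kmh must be >= 0")
    if np.any(np.asarray(rain_mm, dtype=float) < 0.0):
        raise ValueError("rain_mm must be >= 0")


def update_ffmc(prev, tmax_c, rh_pct, wind_kmh, rain_mm):
    """Advance the Fine Fuel Moisture Code by one day.

    Rainfall above the 0.5 mm canopy-interception allowance wets the fuel;
    otherwise the fuel dries (or wets) exponentially toward the
    temperature/humidity/wind-dependent equilibrium moisture content.

    Returns the new FFMC, guaranteed to lie in [0, 101].
    """
    prev = np.asarray(prev, dtype=float)
    if np.any(prev < 0.0) or np.any(prev > 101.0):
        raise ValueError("previous ffmc out of [0, 101]")
    _validate_met(tmax_c, rh_pct, wind_kmh, rain_mm)
    t = np.asarray(tmax_c, dtype=float)
    h = np.asarray(rh_pct, dtype=float)
    w = np.asarray(wind_kmh, dtype=float)
    r = np.asarray(rain_mm, dtype=float)

    # moisture content (%) equivalent of yesterday's code
    mo = 147.2 * (101.0 - prev) / (59.5 + prev)

    raining = r > 0.5
    rf = np.where(raining, r - 0.5, 1.0)  # safe placeholder where dry
    mr = mo + 42.5 * rf * np.exp(-100.0 / (251.0 - mo)) * (1.0 - np.exp(-6.93 / rf))
    mr = mr + np.where(
        mo > 150.0, 0.0015 * (mo - 150.0) ** 2 * np.sqrt(rf), 0.0
    )
    mo = np.where(raining, np.minimum(mr, 250.0), mo)

    ed = (
        0.942 * h**0.679
        + 11.0 * np.exp((h - 100.0) / 10.0)
        + 0.18 * (21.1 - t) * (1.0 - np.exp(-0.115 * h))
    )
    ew = (
        0.618 * h**0.753
        + 10.0 * np.exp((h - 100.0) / 10.0)
        + 0.18 * (21.1 - t) * (1.0 - np.exp(-0.115 * h))
    )

    # drying toward ed
    ko = 0.424 * (1.0 - (h / 100.0) ** 1.7) + 0.0694 * np.sqrt(w) * (
        1.0 - (h / 100.0) ** 8
    )
    kd = ko * 0.581 * np.exp(0.0365 * t)
    m_dry = ed + (mo - ed) * 10.0 ** (-kd)

    # wetting toward ew
    k1 = 0.424 * (1.0 - ((100.0 - h) / 100.0) ** 1.7) + 0.0694 * np.sqrt(w) * (
        1.0 - ((100.0 - h) / 100.0) ** 8
    )
    kw = k1 * 0.581 * np.exp(0.0365 * t)
    m_wet = ew - (ew - mo) * 10.0 ** (-kw)

    m = np.where(mo > ed, m_dry, np.where(mo < ew, m_wet, mo))
    ffmc = 59.5 * (250.0 - m) / (147.2 + m)
    out = np.clip(ffmc, 0.0, 101.0)
    return float(out) if out.ndim == 0 else out


def update_dmc(prev, tmax_c, rh_pct, rain_mm, month):
    """Advance the Duff Moisture Code by one day.

    Rain above 1.5 mm wets the duff layer (with a wetting efficiency that
    decreases as the layer dries out); warm days above the -1.1 °C activity
    floor add a drying increment scaled by the monthly day-length factor.
    """
    prev = np.asarray(prev, dtype=float)
    if np.any(prev < 0.0):
        raise ValueError("previous dmc must be >= 0")
    month = np.asarray(month)
    if np.any(month < 1) or np.any(month > 12):
        raise ValueError("month must be in 1..12")
    _validate_met(tmax_c, rh_pct, 0.0, rain_mm)
    t = np.asarray(tmax_c, dtype=float)
    h = np.asarray(rh_pct, dtype=float)
    r = np.asarray(rain_mm, dtype=float)

    raining = r > 1.5
    re = np.where(raining, 0.92 * r - 1.27, 0.0)
    mo = 20.0 + 280.0 / np.exp(0.023 * prev)
    b = np.where(
        prev <= 33.0,
        100.0 / (0.5 + 0.3 * prev),
        np.where(
            prev <= 65.0,
            14.0 - 1.3 * np.log(np.maximum(prev, 1e-12)),
            6.2 * np.log(np.maximum(prev, 1e-12)) - 17.2,
        ),
    )
    mr = mo + 1000.0 * re / (48.77 + b * re)
    pr = 244.72 - 43.43 * np.log(np.maximum(mr - 20.0, 1e-12))
    dmc_after_rain = np.where(raining, np.maximum(pr, 0.0), prev)

    le = DMC_DAY_LENGTH[month - 1]
    t_eff = np.maximum(t, -1.1)
    k = 1.894 * (t_eff + 1.1) * (100.0 - h) * le * 1.0e-6
    out = np.maximum(dmc_after_rain + 100.0 * k, 0.0)
    return float(out) if out.ndim == 0 else out


def update_dc(prev, tmax_c, rain_mm, month):
    """Advance the Drought Code by one day.

    Rain above 2.8 mm recharges the deep moisture equivalent; potential
    evapotranspiration on warm days (above -2.8 °C) adds a drying
    increment with a monthly day-length adjustment.
    """
    prev = np.asarray(prev, dtype=float)
    if np.any(prev < 0.0):
        raise ValueError("previous dc must be >= 0")
    month = np.asarray(month)
    if np.any(month < 1) or np.any(month > 12):
        raise ValueError("month must be in 1..12")
    _validate_met(tmax_c, 50.0, 0.0, rain_mm)
    t = np.asarray(tmax_c, dtype=float)
    r = np.asarray(rain_mm, dtype=float)

    raining = r > 2.8
    rd = np.where(raining, 0.83 * r - 1.27, 0.0)
    qo = 800.0 * np.exp(-prev / 400.0)
    qr = qo + 3.937 * rd
    dr = 400.0 * np.log(800.0 / qr)
    dc_after_rain = np.where(raining, np.maximum(dr, 0.0), prev)

    lf = DC_DAY_LENGTH[month - 1]
    v = np.maximum(0.36 * (np.maximum(t, -2.8) + 2.8) + lf, 0.0)
    out = np.maximum(dc_after_rain + 0.5 * v, 0.0)
    return float(out) if out.ndim == 0 else out


def compute_isi(ffmc, wind_kmh):
    """Initial Spread Index from FFMC and wind speed (km/h).

    Strictly increasing in wind at fixed FFMC and increasing in FFMC at
    fixed wind; ~0 for saturated fine fuel (FFMC near 0).
    """
    ffmc = np.asarray(ffmc, dtype=float)
    if np.any(ffmc < 0.0) or np.any(ffmc > 101.0):
        raise ValueError("ffmc out of [0, 101]")
    w = np.asarray(wind_kmh, dtype=float)
    if np.any(w < 0.0):
        raise ValueError("wind_kmh must be >= 0")
    m = 147.2 * (101.0 - ffmc) / (59.5 + ffmc)
    fw = np.exp(0.05039 * w)
    ff = 91.9 * np.exp(-0.1386 * m) * (1.0 + m**5.31 / 4.93e7)
    out = 0.208 * fw * ff
    return float(out) if out.ndim == 0 else out


def compute_bui(dmc, dc):
    """Buildup Index from DMC and DC; 0 when DMC is 0, nondecreasing in both."""
    p = np.asarray(dmc, dtype=float)
    d = np.asarray(dc, dtype=float)
    if np.any(p < 0.0) or np.any(d < 0.0):
        raise ValueError("dmc and dc must be >= 0")
    denom = p + 0.4 * d
    safe = denom > 0.0
    denom_safe = np.where(safe, denom, 1.0)
    low = 0.8 * p * d / denom_safe
    high = p - (1.0 - 0.8 * d / denom_safe) * (0.92 + (0.0114 * p) ** 1.7)
    out = np.where(p <= 0.4 * d, low, high)
    out = np.where(safe, np.maximum(out, 0.0), 0.0)
    return float(out) if out.ndim == 0 else out


def step_fwi(state: FwiState, met: MeteoDay, month: int) -> tuple[FwiState, FwiIndices]:
    """One daily step: update the moisture codes, then derive ISI and BUI.

    The standard ordering applies — all three codes are advanced with
    today's weather first, and the indices are computed from the *updated*
    codes.
    """
    ffmc = update_ffmc(state.ffmc, met.tmax_c, met.rh_pct, met.wind_kmh, met.rain_mm)
    dmc = update_dmc(state.dmc, met.tmax_c, met.rh_pct, met.rain_mm, month)
    dc = update_dc(state.dc, met.tmax_c, met.rain_mm, month)
    isi = compute_isi(ffmc, met.wind_kmh)
    bui = compute_bui(dmc, dc)
    return FwiState(ffmc=ffmc, dmc=dmc, dc=dc), FwiIndices(isi=isi, bui=bui)


def step_fwi_arrays(ffmc, dmc, dc, tmax_c, rh_pct, wind_kmh, rain_mm, month,
                    validate: bool = True):
    """Vectorised daily step over a grid; returns (ffmc, dmc, dc, isi, bui).

    ``validate=False`` skips the per-call range checks — for inner loops
    whose inputs were validated once up front.
    """
    if validate:
        ffmc = update_ffmc(ffmc, tmax_c, rh_pct, wind_kmh, rain_mm)
        dmc = update_dmc(dmc, tmax_c, rh_pct, rain_mm, month)
        dc = update_dc(dc, tmax_c, rain_mm, month)
        isi = compute_isi(ffmc, wind_kmh)
        bui = compute_bui(dmc, dc)
        return ffmc, dmc, dc, isi, bui
    t = np.asarray(tmax_c, dtype=float)
    h = np.asarray(rh_pct, dtype=float)
    w = np.asarray(wind_kmh, dtype=float)
    r = np.asarray(rain_mm, dtype=float)

    # FFMC
    mo = 147.2 * (101.0 - ffmc) / (59.5 + ffmc)
    raining = r > 0.5
    rf = np.where(raining, r - 0.5, 1.0)
    mr = mo + 42.5 * rf * np.exp(-100.0 / (251.0 - mo)) * (1.0 - np.exp(-6.93 / rf))
    mr = mr + np.where(mo > 150.0, 0.0015 * (mo - 150.0) ** 2 * np.sqrt(rf), 0.0)
    mo = np.where(raining, np.minimum(mr, 250.0), mo)
    hterm = 0.18 * (21.1 - t) * (1.0 - np.exp(-0.115 * h))
    ed = 0.942 * h**0.679 + 11.0 * np.exp((h - 100.0) / 10.0) + hterm
    ew = 0.618 * h**0.753 + 10.0 * np.exp((h - 100.0) / 10.0) + hterm
    sqw = 0.0694 * np.sqrt(w)
    rate = 0.581 * np.exp(0.0365 * t)
    kd = (0.424 * (1.0 - (h / 100.0) ** 1.7) + sqw * (1.0 - (h / 100.0) ** 8)) * rate
    kw = (
        0.424 * (1.0 - ((100.0 - h) / 100.0) ** 1.7)
        + sqw * (1.0 - ((100.0 - h) / 100.0) ** 8)
    ) * rate
    m = np.where(
        mo > ed,
        ed + (mo - ed) * 10.0 ** (-kd),
        np.where(mo < ew, ew - (ew - mo) * 10.0 ** (-kw), mo),
    )
    ffmc = np.clip(59.5 * (250.0 - m) / (147.2 + m), 0.0, 101.0)

    # DMC
    raining = r > 1.5
    re = np.where(raining, 0.92 * r - 1.27, 0.0)
    mo = 20.0 + 280.0 / np.exp(0.023 * dmc)
    logp = np.log(np.maximum(dmc, 1e-12))
    b = np.where(
        dmc <= 33.0,
        100.0 / (0.5 + 0.3 * dmc),
        np.where(dmc <= 65.0, 14.0 - 1.3 * logp, 6.2 * logp - 17.2),
    )
    mr = mo + 1000.0 * re / (48.77 + b * re)
    pr = 244.72 - 43.43 * np.log(np.maximum(mr - 20.0, 1e-12))
    dmc_r = np.where(raining, np.maximum(pr, 0.0), dmc)
    le = DMC_DAY_LENGTH[month - 1]
    k = 1.894 * (np.maximum(t, -1.1) + 1.1) * (100.0 - h) * le * 1.0e-6
    dmc = np.maximum(dmc_r + 100.0 * k, 0.0)

    # DC
    raining = r > 2.8
    rd = np.where(raining, 0.83 * r - 1.27, 0.0)
    qr = 800.0 * np.exp(-dc / 400.0) + 3.937 * rd
    dc_r = np.where(raining, np.maximum(400.0 * np.log(800.0 / qr), 0.0), dc)
    lf = DC_DAY_LENGTH[month - 1]
    v = np.maximum(0.36 * (np.maximum(t, -2.8) + 2.8) + lf, 0.0)
    dc = np.maximum(dc_r + 0.5 * v, 0.0)

    # indices from updated codes
    m = 147.2 * (101.0 - ffmc) / (59.5 + ffmc)
    isi = 0.208 * np.exp(0.05039 * w) * 91.9 * np.exp(-0.1386 * m) * (
        1.0 + m**5.31 / 4.93e7
    )
    denom = dmc + 0.4 * dc
    safe = denom > 0.0
    denom_safe = np.where(safe, denom, 1.0)
    bui = np.where(
        dmc <= 0.4 * dc,
        0.8 * dmc * dc / denom_safe,
        dmc - (1.0 - 0.8 * dc / denom_safe) * (0.92 + (0.0114 * dmc) ** 1.7),
    )
    bui = np.where(safe, np.maximum(bui, 0.0), 0.0)
    return ffmc, dmc, dc, isi, bui
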