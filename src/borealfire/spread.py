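"""Fire spread rates, elliptical daily growth, extinction, and burned area.

The downwind spread rate v_d is a plant-functional-type (PFT) specific
function of the Initial Spread Index and Buildup Index, derived from the
Canadian Fire Behaviour Prediction system rate-of-spread curves
normalised by their large-ISI / large-BUI limits so that

    v_d = v_d,max * f(ISI) * g(BUI)        (trees)
    v_d = grass blend of cured/green terms  (grasses)

Fire is assumed to grow as an ellipse oriented along the wind, with a
wind-dependent length-to-breadth ratio; the same-day extinction
probability q (a function of population density, standing in for
suppression) converts the one-day burn into the expected area burned over
the fire's exponentially distributed duration; and the representative-
area normalisation converts that to per-PFT burned area in the cell.

All functions are vectorised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpreadParams",
    "SPREAD_CLASSES",
    "isi_scalar",
    "buildup_scalar",
    "spread_rate",
    "length_to_breadth",
    "daily_area",
    "extinguish_prob",
    "area_per_fire",
    "burned_area_pft",
]

SPREAD_CLASSES = ("needleleaf", "broadleaf", "grass")

# (coefficient in exp, power) of the normalised ISI curve per class, and
# the BUI curve constants (scale, rate, reference BUI) for the trees.
_ISI_CURVE = {
    "needleleaf": (0.0232, 1.6),
    "broadleaf": (0.0282, 1.5),
}
_BUI_CURVE = {
    "needleleaf": (0.7568, 17.8337, 64.0),
    "broadleaf": (0.8482, 5.2680, 32.0),
}


@dataclass(frozen=True)
class SpreadParams:
    """Tunables of the spread/area chain.

    ``vdmax_kmh`` maps PFT name to the maximum downwind spread rate
    (km/h).  ``vu_fraction`` sets the upwind (backing) rate as a fraction
    of v_d.  ``lb_scale``/``lb_rate`` parameterise the length-to-breadth
    ratio 1 + lb_scale*(1 - exp(-lb_rate*wind)).  ``a_rep_km2`` is the
    representative area the occurrence probability refers to.
    ``pd_min``/``pd_max`` are the population-density thresholds (persons
    km^-2) between which the extinction probability rises from 0.5
    towards 1.
    """

    vdmax_kmh: dict = field(
        default_factory=lambda: {
            "needleleaf_evergreen": 2.3,
            "needleleaf_continental": 3.8,
            "broadleaf": 0.92,
            "grass": 4.97,
        }
    )
    vu_fraction: float = 0.2
    lb_scale: float = 10.0
    lb_rate: float = 0.06
    fire_day_hours: float = 24.0
    a_rep_km2: float = 800.0
    pd_min: float = 0.001
    pd_max: float = 0.1


DEFAULT = SpreadParams()


def isi_scalar(isi, spread_class: str):
    """Normalised ISI spread scalar in [0, 1) for the tree classes."""
    if spread_class not in _ISI_CURVE:
        raise KeyError(f"no ISI curve for spread class {spread_class!r}")
    c, p = _ISI_CURVE[spread_class]
    isi = np.asarray(isi, dtype=float)
    out = (1.0 - np.exp(-c * isi)) ** p
    return float(out) if out.ndim == 0 else out


def buildup_scalar(bui, spread_class: str):
    """Normalised BUI buildup-effect scalar for the tree classes.

    ``scale * exp(-rate * (1/BUI - 1/bui_ref))``, equal to ``scale`` at
    the reference BUI and approaching 1 as BUI grows without bound; 0 at
    BUI = 0.
    """
    if spread_class not in _BUI_CURVE:
        raise KeyError(f"no BUI curve for spread class {spread_class!r}")
    scale, rate, bui_ref = _BUI_CURVE[spread_class]
    bui = np.asarray(bui, dtype=float)
    if np.any(bui < 0.0):
        raise ValueError("bui must be >= 0")
    safe = np.where(bui > 0.0, bui, 1.0)
    with np.errstate(over="ignore"):  # subnormal BUI: 1/BUI overflows, exp->0
        out = np.where(
            bui > 0.0, scale * np.exp(-rate * (1.0 / safe - 1.0 / bui_ref)), 0.0
        )
    return float(out) if out.ndim == 0 else out


def spread_rate(spread_class: str, vdmax_kmh, isi, bui=None, r_green=None):
    """Downwind spread rate v_d (km/h) for one PFT spread class.

    Trees: ``vdmax * isi_scalar(isi) * buildup_scalar(bui)``.
    Grasses: a blend of the green and cured rate curves weighted by the
    green fraction of grass leaf biomass ``r_green`` (cured grass is the
    faster fuel, with an asymptote of 1.3 * vdmax):

        vdmax * r_green * (1 - exp(-0.031 isi))^1.4
        + 1.3 * vdmax * (1 - r_green) * (1 - exp(-0.035 isi))^1.7
    """
    vdmax = np.asarray(vdmax_kmh, dtype=float)
    if np.any(vdmax <= 0.0):
        raise ValueError("vdmax must be > 0")
    isi = np.asarray(isi, dtype=float)
    if np.any(isi < 0.0):
        raise ValueError("isi must be >= 0")
    if spread_class in ("needleleaf", "broadleaf"):
        if bui is None:
            raise ValueError("tree classes require bui")
        out = vdmax * isi_scalar(isi, spread_class) * buildup_scalar(bui, spread_class)
    elif spread_class == "grass":
        if r_green is None:
            raise ValueError("grass class requires r_green")
        r = np.asarray(r_green, dtype=float)
        if np.any(r < 0.0) or np.any(r > 1.0):
            raise ValueError("r_green out of [0, 1]")
        green = vdmax * r * (1.0 - np.exp(-0.031 * isi)) ** 1.4
        cured = 1.3 * vdmax * (1.0 - r) * (1.0 - np.exp(-0.035 * isi)) ** 1.7
        out = green + cured
    else:
        raise KeyError(f"unknown spread class {spread_class!r}")
    return float(out) if np.ndim(out) == 0 else out


def length_to_breadth(wind_kmh, params: SpreadParams = DEFAULT):
    """Ellipse length-to-breadth ratio: 1 (circular) in calm air, saturating
    at ``1 + lb_scale`` in strong wind."""
    w = np.asarray(wind_kmh, dtype=float)
    if np.any(w < 0.0):
        raise ValueError("wind_kmh must be >= 0")
    out = 1.0 + params.lb_scale * (1.0 - np.exp(-params.lb_rate * w))
    return float(out) if out.ndim == 0 else out


def daily_area(v_d, v_u, lb_ratio, fire_day_hours: float = 24.0):
    """Area burned in one day (km^2) by an elliptical fire.

    The major axis is the head-plus-back run ``(v_d + v_u) * dt`` and the
    breadth is the major axis divided by the length-to-breadth ratio, so

        a_1 = (pi / 4) * L * (L / lb_ratio).
    """
    v_d = np.asarray(v_d, dtype=float)
    v_u = np.asarray(v_u, dtype=float)
    if np.any(v_u < 0.0) or np.any(v_d - v_u < -1e-12):
        raise ValueError("require 0 <= v_u <= v_d")
    lb = np.asarray(lb_ratio, dtype=float)
    if np.any(lb < 1.0):
        raise ValueError("lb_ratio must be >= 1")
    length = (v_d + v_u) * fire_day_hours
    out = (np.pi / 4.0) * length * (length / lb)
    return float(out) if out.ndim == 0 else out


def extinguish_prob(popdens_km2, pd_min: float = 0.001, pd_max: float = 0.1):
    """Same-day fire extinction probability q as a function of population
    density (suppression proxy).

        q = 0.5 + 0.5 * (1 - exp(-pi * (p_d / p_d,max)^v)),
        v = ln(-ln(1 - e^-pi) / pi) / ln(p_d,min / p_d,max),

    which rises from ~0.5 at ``pd_min`` to ~1 at ``pd_max``.  Clamped to
    [0.5, 1).
    """
    if not (0.0 < pd_min < pd_max):
        raise ValueError("require 0 < pd_min < pd_max")
    pd = np.asarray(popdens_km2, dtype=float)
    if np.any(pd < 0.0):
        raise ValueError("population density must be >= 0")
    v = np.log(-np.log(1.0 - np.exp(-np.pi)) / np.pi) / np.log(pd_min / pd_max)
    q = 0.5 + 0.5 * (1.0 - np.exp(-np.pi * (pd / pd_max) ** v))
    out = np.clip(q, 0.5, np.nextafter(1.0, 0.0))
    return float(out) if out.ndim == 0 else out


def area_per_fire(a1_km2, q):
    """Expected area burned over the fire's duration (km^2).

    With an exponential fire-duration distribution set by the daily
    extinction probability q,

        a_r = a_1 * (1 - q) * (2 - q) / q^2.
    """
    a1 = np.asarray(a1_km2, dtype=float)
    if np.any(a1 < 0.0):
        raise ValueError("a1 must be >= 0")
    q = np.asarray(q, dtype=float)
    if np.any(q <= 0.0) or np.any(q > 1.0):
        raise ValueError("q must be in (0, 1]")
    out = a1 * (1.0 - q) * (2.0 - q) / q**2
    return float(out) if out.ndim == 0 else out


def burned_area_pft(p_f, ar_km2, cell_area_km2, f_alpha, a_rep_km2: float = 800.0):
    """Per-PFT burned area in the cell (km^2).

        A_b = P_f * a_r * (A_g * f_alpha) / a_rep,

    capped at the PFT's own extent ``A_g * f_alpha`` (a PFT cannot burn
    more than it covers in a day).
    """
    p_f = np.asarray(p_f, dtype=float)
    if np.any(p_f < 0.0) or np.any(p_f > 1.0):
        raise ValueError("p_f out of [0, 1]")
    f = np.asarray(f_alpha, dtype=float)
    if np.any(f < 0.0) or np.any(f > 1.0):
        raise ValueError("f_alpha out of [0, 1]")
    ag = np.asarray(cell_area_km2, dtype=float)
    ar = np.asarray(ar_km2, dtype=float)
    if np.any(ag < 0.0) or np.any(ar < 0.0):
        raise ValueError("areas must be >= 0")
    extent = ag * f
    out = np.minimum(p_f * ar * extent / a_rep_km2, extent)
    return float(out) if out.ndim == 0 else out
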