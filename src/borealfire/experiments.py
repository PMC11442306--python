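"""Factorial driver attribution, sensitivity analysis and ensemble tests.

The factorial design mirrors the standard attribution protocol for
transient simulations: alongside the full run, one extra run per driver
is performed with that driver's secular trend frozen at its
reference-year level (same seed, same noise).  The contribution of
driver d to the simulated trend is

    c_d = (D_full - D_fixed(d)) / sum_d (D_full - D_fixed(d)),

where D is the end-window minus reference-window mean of the annual
series; contributions are normalised so that, when every driver is
covered, they sum to one.

Sensitivity is summarised by pooling (annual driver mean, annual burned
area) points across all runs, fitting an ordinary least-squares slope and
a LOESS curve (tri-cube locally weighted regression, span 0.75).

Per-cell ensemble significance uses unpaired two-sample t tests between
the reference-period and end-period means of each ensemble member; cells
with P > alpha are flagged "no change" (the stippling convention).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .forcing import ALL_DRIVERS, ScenarioConfig
from .simulate import ModelParams, RunProtocol, RunResult, run_simulation

__all__ = [
    "AttributionResult",
    "run_factorial",
    "trend_delta",
    "factorial_attribution",
    "sensitivity_curves",
    "ensemble_change_test",
    "variance_decomposition",
    "default_ensemble_scenarios",
]

#: Window length (years) of the reference and end periods, mirroring
#: 11-year modern vs end-of-century averaging windows.
DEFAULT_WINDOW = 11


@dataclass(frozen=True)
class AttributionResult:
    """Normalised driver contributions and the raw trend deltas behind them.

    ``defined`` is False when the summed deltas are ~0 (no trend to
    attribute); contributions are NaN in that case.
    """

    contributions: dict  # driver -> [0, 1]
    raw_deltas: dict  # driver -> D_full - D_fixed(d), units of the series
    delta_full: float
    defined: bool


def trend_delta(series: np.ndarray, window: int = DEFAULT_WINDOW) -> float:
    """End-window mean minus start-window mean of an annual series."""
    series = np.asarray(series, dtype=float)
    if len(series) < 2 * window:
        raise ValueError(
            f"series of length {len(series)} too short for two {window}-year windows"
        )
    return float(series[-window:].mean() - series[:window].mean())


def run_factorial(
    protocol: RunProtocol,
    scenario: ScenarioConfig,
    params: ModelParams | None = None,
    drivers: tuple = ALL_DRIVERS,
) -> tuple[RunResult, dict]:
    """Run the full simulation plus one fixed-driver run per driver."""
    full = run_simulation(protocol, scenario, params)
    fixed = {}
    for d in drivers:
        proto_d = dataclasses.replace(protocol, fixed_drivers=frozenset({d}))
        fixed[d] = run_simulation(proto_d, scenario, params)
    return full, fixed


def factorial_attribution(
    full: RunResult,
    fixed_runs: dict,
    window: int = DEFAULT_WINDOW,
    variable: str = "burned_km2",
) -> AttributionResult:
    """Attribute the simulated trend to drivers from a factorial run set.

    All runs must share the scenario seed and differ only in the driver
    held fixed.  ``variable`` selects the annual series to attribute
    (``burned_km2`` or ``co2_kg``).
    """
    d_full = trend_delta(getattr(full, variable), window)
    raw = {
        d: d_full - trend_delta(getattr(run, variable), window)
        for d, run in fixed_runs.items()
    }
    total = sum(raw.values())
    scale = abs(d_full) if d_full != 0.0 else 1.0
    if abs(total) <= 1e-9 * max(scale, 1.0):
        return AttributionResult(
            contributions={d: float("nan") for d in raw},
            raw_deltas=raw,
            delta_full=d_full,
            defined=False,
        )
    contributions = {d: v / total for d, v in raw.items()}
    return AttributionResult(
        contributions=contributions, raw_deltas=raw, delta_full=d_full, defined=True
    )


_DRIVER_COLUMNS = (
    "tmax_c",
    "rh_pct",
    "lightning_km2_yr",
    "popdens_km2",
    "vegc_kgC_m2",
    "rain_mm",
)


def sensitivity_curves(
    runs: list,
    drivers: tuple = _DRIVER_COLUMNS,
    response: str = "burned_mha",
    span: float = 0.75,
) -> dict:
    """Pool annual (driver, burned area) points across runs and summarise.

    Returns, per driver, a dict with the tidy point table, the LOESS
    curve, the OLS slope (response units per driver unit) with its 95%
    confidence interval, and ``defined=False`` for constant drivers.
    """
    if len(runs) < 2:
        raise ValueError("need at least two runs")
    tables = []
    for k, run in enumerate(runs):
        t = run.annual_table()
        t["run"] = k
        tables.append(t)
    pooled = pd.concat(tables, ignore_index=True)
    out = {}
    for drv in drivers:
        x = pooled[drv].to_numpy(dtype=float)
        y = (
            pooled[response].to_numpy(dtype=float)
            if response in pooled
            else getattr(run, response)
        )
        entry = {"points": pooled[[drv, response, "run", "year"]].copy(), "n": len(x)}
        if np.ptp(x) == 0.0:
            entry.update(slope=float("nan"), ci=(float("nan"), float("nan")),
                         curve=None, defined=False)
        else:
            X = np.column_stack([np.ones_like(x), x])
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta
            dof = len(x) - 2
            s2 = resid @ resid / dof
            cov = s2 * np.linalg.inv(X.T @ X)
            se = np.sqrt(cov[1, 1])
            tcrit = stats.t.ppf(0.975, dof)
            entry.update(
                slope=float(beta[1]),
                ci=(float(beta[1] - tcrit * se), float(beta[1] + tcrit * se)),
                curve=lowess(y, x, frac=span, return_sorted=True),
                defined=True,
            )
        out[drv] = entry
    return out


def ensemble_change_test(
    reference_maps: np.ndarray,
    end_maps: np.ndarray,
    alpha: float = 0.05,
):
    """Per-cell unpaired two-sample t test across ensemble members.

    ``reference_maps`` and ``end_maps`` have shape (members, cells...).
    Returns (no_change_mask, p_values): the mask is True where P > alpha,
    i.e. no detectable change (the stippling convention).  Cells where
    both groups are constant and equal are "no change" by definition.
    """
    ref = np.asarray(reference_maps, dtype=float)
    end = np.asarray(end_maps, dtype=float)
    if ref.shape[0] < 2 or end.shape[0] < 2:
        raise ValueError("need at least two ensemble members per group")
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(ref, end, axis=0)
    # identical constant groups give 0/0 -> NaN; that is "no change"
    p = np.where(np.isnan(p), 1.0, p)
    return p > alpha, p


def variance_decomposition(matrix: np.ndarray) -> dict:
    """Two-factor sum-of-squares split of projection spread.

    ``matrix[i, j]`` holds the scalar outcome for climate driver i and
    lightning driver j.  Returns the fractions of total sum of squares
    due to the climate main effect, the lightning main effect, and their
    interaction (residual of the additive model).
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need a 2-D run matrix with at least 2 levels per factor")
    grand = m.mean()
    row = m.mean(axis=1, keepdims=True)
    col = m.mean(axis=0, keepdims=True)
    ss_row = (m.shape[1] * (row - grand) ** 2).sum()
    ss_col = (m.shape[0] * (col - grand) ** 2).sum()
    ss_int = ((m - row - col + grand) ** 2).sum()
    total = ss_row + ss_col + ss_int
    if total == 0.0:
        return {"climate": float("nan"), "lightning": float("nan"),
                "interaction": float("nan")}
    return {
        "climate": float(ss_row / total),
        "lightning": float(ss_col / total),
        "interaction": float(ss_int / total),
    }


def driver_sign_test(runs: list, response: str = "burned_km2") -> dict:
    """Rank-correlation of annual burned area with the primary drivers.

    Temperature, lightning and relative humidity vary within each member
    (seasonally forced weather plus trends), so their correlation is
    computed on within-member anomalies — member-level level differences
    (e.g. different population densities) are removed first.  Population
    density varies *across* members and is correlated on the pooled
    annual values.  Returns driver -> (spearman rho, p value).
    """
    if len(runs) < 2:
        raise ValueError("need at least two ensemble members")
    tables = [r.annual_table().assign(run=k) for k, r in enumerate(runs)]
    pooled = pd.concat(tables, ignore_index=True)
    out = {}
    for col in ("tmax_c", "lightning_km2_yr", "rh_pct"):
        ax = pooled.groupby("run")[col].transform(lambda s: s - s.mean())
        ay = pooled.groupby("run")[response].transform(lambda s: s - s.mean())
        rho, p = stats.spearmanr(ax, ay)
        out[col] = (float(rho), float(p))
    rho, p = stats.spearmanr(pooled["popdens_km2"], pooled[response])
    out["popdens_km2"] = (float(rho), float(p))
    return out


def default_ensemble_scenarios(
    base: ScenarioConfig, n_members: int = 6
) -> list[ScenarioConfig]:
    """The default synthetic ensemble: members differ in seed and in a
    spread of population-density levels (standing in for the multi-model
    forcing spread), while the warming / drying / lightning trends of the
    base scenario apply to all members."""
    pop_factors = np.geomspace(0.2, 5.0, n_members)
    members = []
    for k in range(n_members):
        pop = dataclasses.replace(
            base.population, median_km2=base.population.median_km2 * pop_factors[k]
        )
        members.append(
            dataclasses.replace(base, seed=base.seed + 1000 + k, population=pop)
        )
    return members
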