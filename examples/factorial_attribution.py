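"""Attribute a simulated burned-area trend to its forcing drivers.

Runs a 20-year scenario in which only lightning carries a secular trend,
then re-runs it four times with each driver (climate, lightning,
CO2-driven biomass, population) frozen at its reference-year level —
same seed, same weather noise.  The attribution normalises the
end-minus-start window deltas: with a single trending driver, lightning
should carry ~100% of the trend.
"""

import dataclasses

from borealfire.experiments import factorial_attribution, run_factorial
from borealfire.forcing import LightningConfig, ScenarioConfig, VariableConfig
from borealfire.simulate import RunProtocol

base = ScenarioConfig(nlat=8, nlon=8, years=20, seed=13)
scenario = dataclasses.replace(
    base,
    tmax=dataclasses.replace(base.tmax, trend_per_century=0.0),
    rh=dataclasses.replace(base.rh, trend_per_century=0.0),
    lightning=LightningConfig(trend_frac_per_century=1.5),
    co2_biomass_trend_frac_per_century=0.0,
)

protocol = RunProtocol(years=20, spinup_years=3)
full, fixed = run_factorial(protocol, scenario)
att = factorial_attribution(full, fixed, window=7)

print(f"burned-area trend delta (full run): {att.delta_full:.1f} km^2/yr windowed")
for driver, contrib in sorted(att.contributions.items()):
    print(f"  {driver:<12} contribution: {contrib:6.3f}")
print(
    "\nContributions are normalised to sum to 1; freezing a driver that"
    "\nnever trended leaves the run bit-identical, hence a zero share."
)
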