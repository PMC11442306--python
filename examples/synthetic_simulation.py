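"""Run a small gridded simulation and print the annual fire summary.

Generates a 10x10-cell, 15-year synthetic warming scenario (seasonal
weather with AR(1) noise, summer lightning, heterogeneous population and
vegetation), spins the model up for 20 years, and reports domain burned
area, fire CO2 emissions and their coupling.
"""

import numpy as np

from borealfire import ScenarioConfig, RunProtocol, run_simulation
from borealfire.carbon import emission_intensity

scenario = ScenarioConfig(nlat=10, nlon=10, years=15, seed=7)
result = run_simulation(RunProtocol(years=15, spinup_years=20), scenario)

print(result.annual_table()[
    ["year", "tmax_c", "lightning_km2_yr", "burned_mha", "co2_pg"]
].round(4).to_string(index=False))

r = np.corrcoef(result.burned_km2, result.co2_kg)[0, 1]
intensity = emission_intensity(result.co2_kg.sum(), result.burned_km2.sum() * 1e6)
print(f"\nPearson r (burned area vs fire CO2): {r:.3f}")
print(f"mean fire emission intensity: {intensity:.2f} kg CO2 per m^2 burned")
print(
    "Emissions track burned area almost one-to-one because carbon pools"
    "\nstay near their fire/regrowth equilibrium after spin-up."
)
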