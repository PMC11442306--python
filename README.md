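# borealfire

A process-based, daily-timestep wildfire simulator for boreal
landscapes, written for fire ecologists and carbon-cycle modellers who
want a transparent, testable implementation of a fire-weather-driven
burned-area and fire-emissions scheme — without coupling to a full land
surface model.  Everything runs on synthetic, fully reproducible gridded
forcing, so the model's process chain can be exercised, perturbed and
attributed on a laptop; CF-convention NetCDF readers accept real forcing
where available.

## The model

Fire weather is summarised by the Canadian Fire Weather Index (FWI)
system: daily maximum temperature, relative humidity, wind and rainfall
drive the Fine Fuel Moisture Code (FFMC), Duff Moisture Code (DMC) and
Drought Code (DC), from which the Initial Spread Index (ISI) and Buildup
Index (BUI) follow.

The probability that a fire occurs in a representative area
(a_rep = 800 km²) of a grid cell on a given day is a product of three
conditional probabilities,

    P_f = P_b · P_i · P_m

* **P_b** (fuel availability) ramps linearly in aboveground biomass
  between 0.2 and 1.0 kg C m⁻²;
* **P_i** (ignition) combines a lightning ramp (0 at 0.25, 1 at
  10 strikes km⁻² yr⁻¹) with a human-ignition term that saturates at
  300 persons km⁻², via p_i = p_nat + (1 − p_nat)·p_hum;
* **P_m** (fuel moisture) is the logistic
  e^(−25.2 + 0.34·FFMC) / (1 + e^(−25.2 + 0.34·FFMC)).

A fire grows as a wind-aligned ellipse.  The downwind spread rate v_d is
the plant-functional-type maximum v_d,max (2.3 / 3.8 / 0.92 / 4.97 km/h
for the default needleleaf, continental needleleaf, broadleaf and grass
types) scaled by ISI- and BUI-dependent factors normalised to unit
infinite-index limits; grasses blend separate cured and green curves by
the green leaf fraction r_green.  The same-day extinction probability

    q = 0.5 + 0.5·(1 − e^(−π (p_d / p_d,max)^v)),
    v = ln(−ln(1 − e^(−π)) / π) / ln(p_d,min / p_d,max)

rises from ≈0.5 at p_d,min = 0.001 to ≈1 at p_d,max = 0.1 persons km⁻²
(suppression), and with an exponential fire-duration distribution the
expected area per fire is a_r = a_1 (1 − q)(2 − q)/q².  Per-PFT burned
area is A_b = P_f · a_r · (A_g f_α)/a_rep, capped at the PFT extent.

Burned fractions are applied to per-PFT carbon pools (leaf, stem, root,
litter, soil) with per-pool emission fractions and live-pool mortality
fractions; emitted carbon leaves as CO₂ (×44/12), killed carbon moves to
litter, and pools regrow toward carrying capacity.  The synthetic
forcing generator, delta-method lightning bias correction, factorial
driver attribution, sensitivity curves and ensemble t-tests round out
the toolkit.

## Worked example

`examples/synthetic_simulation.py` runs a 10×10-cell, 15-year warming
scenario after a 20-year spin-up and prints (abridged):

```
 year  tmax_c  lightning_km2_yr  burned_mha  co2_pg
    0  0.2328            0.6687      0.0786  0.0039
    1  0.5858            0.7305      0.0841  0.0044
    2  0.0259            1.0562      0.1290  0.0063
  ...
   13  1.0007            1.6539      0.1882  0.0091
   14  0.1441            1.1757      0.1007  0.0045

Pearson r (burned area vs fire CO2): 0.989
mean fire emission intensity: 4.94 kg CO2 per m^2 burned
```

Each row is a domain-wide annual summary: mean daily-maximum
temperature (°C), annualised cloud-to-ground lightning
(strikes km⁻² yr⁻¹), burned area (Mha) and fire emissions (Pg CO₂).
Active lightning years (e.g. year 13) burn the most area, and emissions
track burned area almost one-to-one because the carbon pools sit near
their fire/regrowth equilibrium after spin-up.

The other scripts in `examples/` each demonstrate one capability:
stepping the fire-weather codes through a season, the
occurrence-to-burned-area chain for a single cell-day, delta-method
lightning bias correction, and factorial driver attribution.

A thin CLI wraps the same library calls:

```sh
borealfire synth --years 5 --out forcing.nc
borealfire run --years 30 --out results/
borealfire factorial --years 30 --out attribution.json
```

## Layout

| path | contents |
| --- | --- |
| `src/borealfire/fwi.py` | FFMC/DMC/DC codes and ISI/BUI indices |
| `src/borealfire/occurrence.py` | P_b, P_i, P_m and their product |
| `src/borealfire/spread.py` | spread rates, ellipse, extinction, burned area |
| `src/borealfire/carbon.py` | combustion, mortality, CO₂ accounting |
| `src/borealfire/forcing.py` | synthetic scenarios, delta corrections, regrowth |
| `src/borealfire/simulate.py` | the daily gridded run loop |
| `src/borealfire/experiments.py` | factorial attribution, sensitivity, t-tests |
| `src/borealfire/io.py`, `cli.py`, `config.py` | NetCDF/CSV/YAML, manifests, CLI |

See `docs/methods.md` for model assumptions, parameter provenance and
known limitations — in particular, the bundled combustion fraction table
is a synthetic placeholder meant to be overridden for quantitative work.
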