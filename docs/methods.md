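# Methods

## Scope and design

`borealfire` implements a fire-weather-driven burned-area and fire
carbon-emission scheme of intermediate complexity, of the kind embedded
in land surface models, as a standalone package.  The deliberate
boundary: everything *fire* (weather codes, occurrence, spread, burned
area, combustion) is modelled mechanistically; everything *vegetation*
(photosynthesis, allocation, competition) is replaced by a minimal
carrying-capacity regrowth closure, because the aim is to study the fire
module's behaviour, not to re-build a land surface scheme.  The model is
deterministic: the fire occurrence probability enters burned area as an
expected value, never as a random draw, so all stochasticity in a
simulation is inherited from the forcing.

## Fire weather

The standard Canadian FWI equation set is implemented for FFMC, DMC, DC,
ISI and BUI, driven by daily maximum temperature (not noon values), with
the single-table monthly day-length factors.  DMC and DC are carried as
internal state because BUI is defined from them, even though only FFMC,
ISI and BUI feed the fire module.  Start-up values are the conventional
FFMC 85 / DMC 6 / DC 15.  Overwintering adjustment of DC, hourly FFMC,
the composite FWI index and the Daily Severity Rating are out of scope.

Two numerical quirks of the published equation set are preserved rather
than "fixed", and the tests are written around them:

* the FFMC code↔moisture conversion pair is not an exact algebraic
  inverse (numerators 14875 vs 147.2·101 = 14867.2).  Under constant
  drying weather this adds a slow linear approach phase, so equilibrium
  is reached in ~35–40 days from FFMC 85 rather than ~10;
* the high-DMC branch of the BUI correction term makes BUI very slightly
  non-monotone in DMC below DMC ≈ 1 (order 10⁻³ at BUI ≈ 0.15); the
  monotonicity property is asserted for DMC ≥ 1.

## Occurrence, spread and burned area

Parameters printed in the module equations are hard defaults,
overridable from YAML: biomass thresholds 0.2/1.0 kg C m⁻², lightning
thresholds 0.25/10 strikes km⁻² yr⁻¹ (daily strike densities are
annualised ×365.25 before comparison), human-ignition saturation at 300
persons km⁻², P_m logistic coefficients (−25.2, 0.34), spread maxima
{2.3, 3.8, 0.92, 4.97} km/h, extinction thresholds p_d,min = 0.001 and
p_d,max = 0.1 persons km⁻², representative area 800 km².  The natural
ignition ramp is linear (the simplest form consistent with its two
saturation thresholds), and natural and human ignition combine
complementarily, p_i = p_nat + (1 − p_nat)·p_hum.  The logit of P_m is
taken at face value: P_m *increases* with FFMC, consistent with the
standard convention that high FFMC means dry, ignitable fuel.

Three quantities the module needs are not fixed by the printed
equations and use conventional forms, isolated behind configuration:
the upwind (backing) spread rate v_u = 0.2·v_d; the length-to-breadth
ratio lb(w) = 1 + 10(1 − e^(−0.06 w)); and a fire-day length of 24 h in
the one-day ellipse area.  The exponent v of the extinction probability
is computed with natural logarithms, which reproduces the curve's
documented endpoints (q = 0.5216 at p_d,min, 0.9784 at p_d,max).
Per-PFT burned area is capped at the PFT's own extent as a safeguard at
extreme parameter values.

## Carbon accounting

Per fire event, each pool loses pool·burned_fraction·ʊ (combusted,
emitted as CO₂ with the 44/12 mass ratio) and each live pool
additionally moves pool·burned_fraction·ϴ to litter (fire kill).  Soil
combustion is a single bulk fraction standing for depth distribution and
average combustibility; no depth-of-burn, smoldering/flaming split or
non-CO₂ species.  Carbon is conserved exactly per event (asserted to
1e-12 relative).

**The bundled ʊ/ϴ table (`data/combustion.yaml`) is a synthetic
placeholder**: values follow the usual combustion ranking
(litter > leaf > soil > stem ≈ root) but are not transcriptions of any
published per-PFT table, and the output metadata says so.  Override the
table from configuration for quantitative work.

## Synthetic forcing

The generator emulates the statistical structure of boreal fire-model
forcing.  Per variable: a seasonal cosine (mid-summer peak, day 200 of a
365-day no-leap calendar), cell-level AR(1) anomalies, a *domain-wide*
AR(1) anomaly (σ 1.5 °C for temperature, 4 % for RH, persistence 0.95)
standing in for synoptic/continental-scale weather — without it,
cell-independent noise averages out of domain totals and interannual
variability collapses — and an additive linear trend.  RH is coupled to
the temperature anomaly at −1.2 % °C⁻¹.  Rain is Bernoulli wet days
(35 %) with exponential amounts (mean 6 mm).  Lightning has a Gaussian
summer season (width 45 d) scaled to a 1.0 strikes km⁻² yr⁻¹
climatology, log-normal daily and static spatial multipliers, a
per-year activity multiplier (σ_log 0.3, active vs quiet seasons) and a
fractional trend.  Population density is a static log-normal field
(median 0.03 km⁻², σ_log 1.5, spanning the extinction curve's
thresholds).  A CO₂-fertilisation stand-in multiplies live-pool carrying
capacities by a fractional trend.  Default trends (+4 °C, −5 % RH, +50 %
lightning, +20 % biomass capacity per century) describe a
rapid-warming-scenario-like storyline.

Every variable draws from its own named random stream derived from the
scenario seed, so adding or perturbing one variable never changes
another — this is also what makes factorial runs differ *only* in the
frozen trend.  Known limitations relative to real forcing: no spatial
correlation of weather beyond the single domain mode, no
lightning–convection coupling to the simulated weather, no orography,
and land cover fixed in time.  Passing tests therefore demonstrate the
process chain and its sensitivities, not quantitative agreement with any
observed fire record.

Grid default: 20×20 cells of 576 km² (≈0.22°), so the representative
area a_rep = 800 km² is of the same order as a cell.

## Delta-method bias correction

Multiplicative: per-cell scaling so the series mean equals the target
climatology; conserves the target's cumulative total exactly and
preserves relative variability; cells with zero source climatology and
nonzero target are flagged and left uncorrected.  Additive: per-cell
offset; negative strike densities are clamped at zero with the clamp
mass accounted for (the corrected mean exceeds the target by exactly the
clamped mass per step).

## Simulation protocol and experiments

A run spins up with *all* trends frozen at the reference year (default
60 years, ≈1.5 e-folding times of the slowest live pool, which brings
the fire/regrowth pool balance near equilibrium) and then records the
transient.  Live-pool regrowth e-folding times are 40/30/3 years for
trees/broadleaf/grass, litter 20, soil 100 years.

Factorial attribution re-runs the scenario with each driver's trend
frozen at the reference year (climate, lightning, CO₂-biomass,
population) and normalises the end-window minus reference-window deltas
(11-year windows by default):
c_d = (Δ_full − Δ_fixed(d)) / Σ_d (Δ_full − Δ_fixed(d)).  Because the
streams are named, a fixed run differs from the full run *only* in the
frozen trend; a driver that never trended contributes exactly zero.  A
near-zero denominator is flagged undefined rather than normalised.

Sensitivity analysis pools annual (driver, burned area) points across
runs and reports an OLS slope with 95 % CI plus a LOESS curve (tri-cube
locally weighted regression, span 0.75 — a conventional default).
Ensemble change detection uses unpaired two-sample t tests per cell
between reference- and end-period means across members (the unpaired
choice is deliberate; members are treated as exchangeable), masking
cells with P > α as "no change".  Projection-spread decomposition uses a
two-factor sum-of-squares split (climate, lightning, interaction) over a
run matrix.

The default ensemble varies the member seed and spreads population
density geometrically (0.2–5× the base median) as a stand-in for
multi-model forcing spread.  Driver-sign diagnostics correlate burned
area with temperature, lightning and RH on within-member anomalies (so
member-level differences don't dilute the weather signal) and with
population density on pooled values (it only varies across members).

## Numerical choices and problem sizes

All daily updates are vectorised over cells; the run loop uses a
PFT-batched kernel that the test suite proves equivalent to composing
the public per-component functions.  Division guards: BUI = 0 at
DMC = DC = 0; spread scalar 0 at BUI = 0; burned fraction 0 at zero PFT
extent; emission intensity NaN at zero burned area.  q is clamped to
[0.5, 1) so the fire-duration multiplier stays finite.  Tests and
examples use 2×2 to 20×20 grids and 1–50-year transients — sizes chosen
so the full suite exercises every protocol (including a 20×20, 50-year
factorial and a six-member 30-year ensemble) in minutes on one core.

## Known limitations

No crown/surface fire distinction, slope effects, fuel-consumption
feedback on spread, sub-daily growth, peatland soils, overwintering
fire, or non-CO₂ species.  Vegetation dynamics are a relaxation toward
prescribed carrying capacities, so long-term vegetation–fire feedbacks
(composition shifts, fuel build-up from succession) are outside the
model's reach.  The placeholder combustion table makes absolute emission
levels illustrative, though the emission *intensity* the defaults yield
(≈4.4–4.9 kg CO₂ m⁻² burned) sits in the range typical of boreal
landscapes.
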