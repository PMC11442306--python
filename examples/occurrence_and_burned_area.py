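"""From fire weather to expected burned area for one cell-day.

Walks the full per-cell chain for a dry, windy July day in a
needleleaf-dominated 576 km^2 grid cell: occurrence probability
(biomass x ignition x moisture), downwind spread rate, elliptical
one-day burn, extinction-weighted fire-duration area, and the
representative-area scaling to expected burned area.
"""

from borealfire import occurrence, spread

ffmc, isi, bui = 92.0, 10.4, 80.0  # after a two-week dry spell
wind_kmh = 18.0
lightning = 2.4  # strikes km^-2 yr^-1 (annualised from the daily density)
popdens = 0.04  # persons km^-2: remote managed forest
agb = 3.2  # kg C m^-2 aboveground biomass
cell_area, f_needle = 576.0, 0.55

p_b = occurrence.prob_biomass(agb)
p_m = occurrence.prob_moisture(ffmc)
p_i = occurrence.prob_ignition(lightning, popdens)
p_f = occurrence.prob_fire(p_b, p_i, p_m)
print(f"P_b={p_b:.3f}  P_i={p_i:.3f}  P_m={p_m:.3f}  ->  P_f={p_f:.4f}")

v_d = spread.spread_rate("needleleaf", 2.3, isi=isi, bui=bui)
lb = spread.length_to_breadth(wind_kmh)
a1 = spread.daily_area(v_d, 0.2 * v_d, lb)
q = spread.extinguish_prob(popdens)
ar = spread.area_per_fire(a1, q)
ab = spread.burned_area_pft(p_f, ar, cell_area, f_needle)
print(f"spread rate v_d = {v_d:.2f} km/h, ellipse L/B = {lb:.2f}")
print(f"one-day burn a_1 = {a1:.1f} km^2, extinction q = {q:.3f}")
print(f"area per fire a_r = {ar:.1f} km^2")
print(f"expected burned area of the needleleaf fraction: {ab:.2f} km^2")
print(
    "\nP_f is the chance a fire occurs in a representative 800 km^2; the"
    "\nexpected burn scales it by the fire size and the PFT's extent."
)
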