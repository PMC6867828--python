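"""Saturating filament growth from the three-reaction elongation cycle.

Simulates single filaments over a profilin-actin concentration ladder,
fits the resulting velocity curve with the hyperbolic saturation law and
with a low-concentration linear model, and compares the fitted
parameters with the generating rate constants.
"""

import actinpace as ap
from actinpace.synthetic import WT_CYCLE_RATES, gen_velocity_curve

curve, truth = gen_velocity_curve(seed=7, n_filaments=40, duration=30.0,
                                  mode="simulate")
for c, v, sd in zip(curve.conc, curve.v_mean, curve.v_sd):
    print(f"[PA] = {c * 1e6:6.1f} uM  ->  v = {v:6.1f} +/- {sd:5.1f} subunits/s")

fit = ap.fit_hyperbolic(curve)
lin = ap.fit_linear_regime(curve, conc_cutoff=10e-6)
print()
print(f"v_max  : {fit.v_max:6.1f} subunits/s   (truth {truth['v_max']:.1f})")
print(f"K_0.5  : {fit.k_half * 1e6:6.1f} uM          (truth {truth['k_half'] * 1e6:.1f})")
print(f"low-concentration slope: {lin.slope:.2e} /M/s (k_bind {truth['k_bind']:.2e})")
print()
print("Growth is linear only well below K_0.5; at cellular concentrations")
print("(50-200 uM) the velocity sits on the plateau set by profilin release,")
print(f"about {ap.cycle_velocity(WT_CYCLE_RATES, 150e-6):.0f} subunits/s here.")
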