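"""Formin polymerase activity across the full substrate range.

Computes the relative velocity enhancement of an mDia1-like formin
(accelerating profilin-actin binding 6x and profilin release 6x) over
free barbed ends, from the binding-limited to the release-limited regime,
and fits the synthetic formin velocity curve for the plateau enhancement.
"""

import numpy as np

import actinpace as ap
from actinpace.synthetic import FORMIN_FACTORS, WT_CYCLE_RATES, gen_formin_curves

factors = FORMIN_FACTORS["mDia1"]
for mult in [0.05, 0.2, 1.0, 5.0, 20.0]:
    k_half = ap.hyperbolic_params_from_cycle(WT_CYCLE_RATES).k_half
    enh = ap.relative_enhancement(WT_CYCLE_RATES, factors, mult * k_half)
    print(f"[PA] = {mult:5.2f} x K_0.5  ->  enhancement {enh:.2f}x")

curves, _ = gen_formin_curves(seed=7, mode="fast")
free = ap.fit_hyperbolic(curves["free"])
dia1 = ap.fit_hyperbolic(curves["mDia1"])
print()
print(f"fitted free-end plateau : {free.v_max:7.1f} subunits/s")
print(f"fitted mDia1 plateau    : {dia1.v_max:7.1f} subunits/s")
print(f"plateau enhancement     : {dia1.v_max / free.v_max:.2f}x")
print()
print("The enhancement decreases only mildly from the binding-limited limit")
print("(f_bind) to the plateau ratio: formins act as pacemakers, raising the")
print("speed limit itself rather than merely the binding frequency.")
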