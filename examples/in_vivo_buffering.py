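"""Buffered formin speeds in cells: velocity vs. profilin-actin level.

Generates single-molecule formin velocity distributions for a wild-type
and a 2.6-fold overexpressing condition, fits Gaussians, and compares a
proportional (through-origin) model against the saturation law to show
that near-saturation a large concentration change moves the speed only
marginally.
"""

import actinpace as ap
from actinpace.synthetic import gen_single_molecule_velocities

base = ap.HyperbolicFit(v_max=2000.0, k_half=29e-6)  # mDia1-like cycle
c_wt, fold = 150e-6, 2.6

dists = []
for label, conc in [("wt", c_wt), ("overexpressing", fold * c_wt)]:
    df, _ = gen_single_molecule_velocities(
        seed=7 if label == "wt" else 8, mu=float(base.velocity(conc)),
        sigma_mol=300.0,
    )
    fit = ap.fit_gaussian_velocity(df["velocity"], cell_ids=df["cell_id"])
    dists.append(fit)
    print(f"{label:15s}: {fit.mu:7.1f} +/- {fit.sigma:5.1f} subunits/s "
          f"(n = {fit.n_molecules})")

table, prop, hyper = ap.velocity_vs_concentration(
    dists, [1.0, fold],
)
ratio = dists[1].mu / dists[0].mu
print()
print(f"velocity ratio for a {fold:.1f}-fold concentration rise : {ratio:.3f}")
print(f"model prediction {ap.buffering_ratio(base, c_wt, fold):.3f} "
       "(a proportional response would give 2.6)")
print()
print("Operating at ~5x K_0.5, a 2.6-fold rise in profilin-actin moves the")
print("formin speed by only ~10%: elongation is buffered near saturation.")
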