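# Methods

## The elongation-cycle model

Barbed-end growth from profilin–actin is modelled as a sequential,
irreversible three-reaction cycle: (1) binding of a profilin–actin
complex to the free end, second order in the total profilin–actin
concentration *c* with rate constant *k*<sub>bind</sub>; (2) the
first-order structural monomer-to-filament transition *k*<sub>trans</sub>;
(3) first-order profilin release from the terminal protomer
*k*<sub>release</sub>. The mean cycle time is the sum of the three mean
step durations, so the steady-state velocity is

v(c) = [1/(k_bind·c) + 1/k_trans + 1/k_release]⁻¹,

which is algebraically identical to the hyperbola
v_max·c/(K₀.₅ + c) with v_max = (1/k_trans + 1/k_release)⁻¹ and
K₀.₅ = v_max/k_bind. This identity is exact, not asymptotic; the test
suite asserts it to 1e-12 relative over dense grids.

Assumptions and their consequences:

- **Irreversibility of binding.** Unbinding of profilin–actin before the
  transition would renormalize the effective k_bind without changing the
  hyperbolic form; since velocity data identify only (v_max, K₀.₅), the
  reversible variant is observationally equivalent and is omitted.
- **Lumped first-order steps.** v_max depends on k_trans and k_release
  only through 1/k_trans + 1/k_release. Velocity data alone cannot split
  the sum; the package reports the lumped v_max and documents this
  degeneracy. Defaults put 10% of the saturated cycle time in the
  transition (k_trans = 5000 /s) and 90% in release (k_release = 556 /s).
- **No depolymerization in cycle mode.** Growth velocities of hundreds
  of subunits/s dwarf barbed-end off-rates (~1 /s), so the cycle is a
  pure forward renewal process. The bare-actin mode is a birth–death
  process (gain k₊·c, loss k₋, length floored at zero) for the
  profilin-free control regime, where loss is not negligible.
- **Concentration convention.** The cycle takes the *total*
  profilin–actin concentration. Free-species corrections for assay mixes
  containing excess profilin or thymosin-β4 are applied upstream with
  the competition solver, not inside the cycle.

Formins multiply k_bind by f_bind (FH1-mediated delivery) and k_release
by f_release (FH2 action at the end); k_trans is left unmodified, since
velocity curves provide no handle on a formin effect on the transition.
The relative enhancement v_formin(c)/v_free(c) then decreases
monotonically from f_bind at c → 0 to the v_max ratio at saturation and
always lies between the two.

## Stochastic simulation

`simulate_filament` draws an exact realization of the cycle: the end
state walks free → capped-pre-transition → capped-post-transition →
free, with exponential waiting times; the length increments at the
binding event and end occupancy is tracked separately (matching the
structural picture of a transiently profilin-capped end). Because whole
cycles are sums of independent exponentials, batches of cycles are drawn
vectorized without approximation. One seeded generator per run; the seed
is recorded in every trajectory, and identical seeds give bit-identical
trajectories. An event cap (default 1e7) guards runaway parameter sets;
hitting it raises an error carrying the partial trajectory.

Velocity is estimated as the least-squares slope of length vs. time over
all event points (mirroring kymograph slope analysis, rather than
endpoint differencing), with 2.7 nm per subunit for µm/s conversion.

## Binding equilibria

The two-ligand competition (profilin and a probe competing for actin
monomers) reduces to a cubic in the free actin concentration, solved in
the closed trigonometric form. Two numerical guards apply: the arccos
argument is clamped when floating-point noise pushes it marginally past
[−1, 1] (tolerance 1e-9; beyond that the solver falls back to bisection),
and the root is polished with up to three Newton steps on the
conservation equation, because the trigonometric expression loses about
half the mantissa to cancellation when free actin is many orders of
magnitude below the totals. Every solution is verified against
conservation (1e-10 relative) and mass action (1e-8 relative); failures
fall back to bracketed root-finding and, if still violating tolerance,
raise.

The anisotropy observable is modelled as linear in the *bound-probe
fraction* (r = r_f + (r_b − r_f)·wa/w_total), which keeps the observable
dimensionless; a literal variant linear in the profilin–actin
concentration is retained behind `mode="printed"` for auditing published
formulas. Similarly, the quench isotherm divides the bound-complex
quadratic root either by the titrant total (`normalization="titrant"`,
the literal published form, undefined at zero titrant) or by the labeled
actin total (`normalization="actin"`, the physically motivated bound
fraction of the fluorescent species). The fitter and generator default
to the actin normalization so titrations that start at zero titrant can
be used whole.

Fits are unweighted least squares unless per-point errors are supplied
(then inverse-variance). Affinities are fitted on a log scale with the
standard error mapped back by the delta method. Titrations are sorted by
titrant concentration; duplicates are treated as replicates.

## Stopped-flow kinetics

Traces are fitted with I(t) = (I_f − I_b)·exp(−k_obs·t) + I_b, with
initial guesses from the endpoints and a log-linearized slope; optional
time-origin and linear-drift terms are off by default. A warning is
emitted when a trace spans fewer than 3 e-folding times or when the
titrant is not in ≥10-fold excess over actin (the pseudo-first-order
assumption). k_on is the slope of k_obs vs. titrant concentration; the
intercept is estimated, not pinned at zero, because it equals k_off
under the relaxation model and provides an independent check. k_off is
computed as K_D·k_on with first-order Gaussian propagation
σ² = (k_on·σ_KD)² + (K_D·σ_kon)²; the tests verify this against
Monte-Carlo propagation in the small-relative-error regime where the
first-order formula is accurate (a few percent relative errors; at
relative errors above ~5% on inverse-variate chains, second-order terms
contribute at the percent level).

## Cellular quantitation

Per-cell concentration: mass_per_cell = (intensity/slope)/n_cells from
the standard-curve slope (the fitted intercept is reported for QC but
not used in inversion), then concentration = mass_per_cell/(MW ·
fraction · mean volume). Dividing the lane mass by the number of cells
loaded is the only dimensionally consistent reading of the published
arithmetic. The accessible-volume `fraction` defaults to 0.5 (profilin
and actin are excluded from the endomembrane system, roughly half the
cell volume), bounding a maximal two-fold overestimate; it is
configurable. Molecular weights default to 42 kDa (actin) and 15 kDa
(profilin).

Distribution fits use maximum likelihood on raw samples rather than
least squares on histogram bins — bin-free, reproducible, and
asymptotically equivalent to the histogram fits used in practice.
Lognormal cell volumes report the mean exp(µ + σ²/2) and SD of the
fitted distribution; Gaussian velocity fits report asymptotic standard
errors (σ/√n, σ/√2n) and offer a per-cell mode that averages molecules
within cells before fitting, since published protocols are ambiguous
about pooling.

## Synthetic data: what it emulates and what it does not

The generators reproduce each assay's *statistical structure*: additive
Gaussian anisotropy noise, multiplicative intensity noise, exponential
stopped-flow decays with k_obs linear in titrant, per-filament velocity
dispersion (exact stochastic simulation, or a fast Gaussian mode),
hierarchical per-cell/per-molecule velocity sampling, and lognormal cell
volumes. Defaults follow the study designs: 4 nM probe with 150 nM actin
titrated 0–20 µM; quench titrations 0–200 µM; six-concentration
stopped-flow ladders against 0.5 µM actin; twelve concentrations 1–175 µM
with 40 filaments each; ≥10 cells × 65 molecules for in vivo velocity
distributions; ≥300 cell volumes.

Noise magnitudes (anisotropy SD 0.002, intensity CV 5%, per-filament
velocity CV 15% in fast mode) are package conventions chosen to match
the visual scale of published error bars; they are not measured
quantities. Passing recovery tests therefore demonstrates correctness of
the estimators under these conventions, not instrument-level accuracy on
real data. The generators do not model photophysics, tracking errors,
instrument dead time, baseline drift, or image-level artifacts.

Generating truths are chosen once from the measured landscape: wild-type
cycle rates k_bind = 1.16e7 /M/s (the canonical barbed-end association
rate constant, which profilin–actin matches), k_trans = 5000 /s,
k_release = 556 /s, giving v_max ≈ 500 subunits/s and K₀.₅ ≈ 43 µM —
reproducing the observed regime structure (near-linear below 10 µM,
strongly sub-linear above 20 µM, approaching saturation at ≥100 µM).
Mutant panels scale k_release by {0.2, 1, 1.5, 4} for the tight-binding
double mutant, wild type, and the two release-accelerated single
mutants. Formin release factors are calibrated against observed
plateaus: with the transition carrying 10% of the saturated cycle time,
f_release = 6.0 yields the 4-fold mDia1 plateau enhancement
(2000 subunits/s) and f_release = 1.77 the ~820 subunits/s mDia2
plateau; f_bind values (6, 4, 2.5) set the low-concentration enhancement.

## Tolerances and pre-registered recovery bands

Exactness checks (solver vs. independent bisection oracle, hyperbolic
identity) use 1e-8/1e-12 relative bounds. Stochastic checks compare
grand means against analytic values within 3 standard errors at 100
filaments per condition. Recovery bands for the noisy binding fitters
were frozen from a 200-seed Monte-Carlo run at the default designs and
noise levels: 95th-percentile relative errors of 0.31 (competition Kd)
and 0.36 (quench Kd), reflecting the information content of a single
12-point titration at those noise levels — medians are ~0.12–0.14.
Velocity-curve recovery at the full design (12 × 40 filaments × 30 s) is
within 10% for (v_max, K₀.₅) and 15% for the low-concentration slope;
the slope band is dominated by the systematic secant bias of fitting a
line to a hyperbola over 1–10 µM (≈0.86 of k_bind at K₀.₅ = 43 µM), not
by noise.

## Degenerate inputs and tie-breaks

Zero receptor or zero ligands short-circuit the competition solver to
the trivial equilibria. Zero concentration gives zero velocity and an
eventless trajectory. Exact-event simulation cannot produce simultaneous
events. Flat titrations and flat traces are rejected with an
identifiability warning or fit error rather than returning arbitrary
parameters. The bare-filament boundary at length zero permits only gain
events.

## Known limitations

Force-dependent elongation, filament nucleation, ATP-hydrolysis state
tracking, pointed-end dynamics and multi-filament networks are out of
scope. The cycle model cannot separate k_trans from k_release using
velocity data alone. More than two competing monomer-binding species,
cooperative binding, and kinetic (non-equilibrium) titrations are not
supported.
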