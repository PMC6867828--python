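"""Exact equilibrium solvers and fitters for actin monomer-binding assays.

Two assay families are covered:

* **Two-ligand competition** — profilin (P) and a fluorescent probe
  (Atto488-WAVE1-WCA, or thymosin-beta4) compete for actin monomers (A).
  The coupled mass-action equations reduce to a cubic in the free actin
  concentration, solved here in closed trigonometric form with a
  bisection fallback for numerically degenerate cases.  Fluorescence
  anisotropy of the probe reads out the competition and is fitted to
  extract the competitor affinity.
* **Single-site ligand-depletion binding** — a fluorescence-quench
  titration (thymosin-beta4 against IAEDANS-actin) fitted with the
  quadratic binding isotherm, which remains exact when the titrant
  depletes the labeled species.

All concentrations are molar.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import lmfit
import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import (
    ConvergenceError,
    FitError,
    IdentifiabilityWarning,
    InvalidInputError,
)

__all__ = [
    "AffinityConstant",
    "CompetitionMixture",
    "SpeciesState",
    "AnisotropyEndpoints",
    "QuenchEndpoints",
    "TitrationSeries",
    "CompetitionFit",
    "QuenchFit",
    "solve_two_ligand_competition",
    "predict_anisotropy",
    "fit_competition_affinity",
    "predict_quench",
    "fit_quench_affinity",
    "free_species_table",
]


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AffinityConstant:
    """Equilibrium dissociation constant (molar) with optional standard error."""

    kd: float
    kd_err: Optional[float] = None

    def __post_init__(self):
        if not np.isfinite(self.kd) or self.kd <= 0:
            raise InvalidInputError(f"kd must be positive and finite, got {self.kd}")
        if self.kd_err is not None and (not np.isfinite(self.kd_err) or self.kd_err < 0):
            raise InvalidInputError(f"kd_err must be >= 0, got {self.kd_err}")


@dataclass(frozen=True)
class CompetitionMixture:
    """Total concentrations and affinities of a two-ligand, one-receptor mix.

    The receptor is the actin monomer pool (``a_total``); the two ligands
    are the competitor (profilin, ``p_total``, affinity ``kp``) and the
    probe (WAVE1-WCA or thymosin-beta4, ``w_total``, affinity ``kw``).
    """

    a_total: float
    p_total: float
    w_total: float
    kp: AffinityConstant
    kw: AffinityConstant

    def __post_init__(self):
        for name in ("a_total", "p_total", "w_total"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise InvalidInputError(f"{name} must be >= 0 and finite, got {v}")

    def with_p_total(self, p_total: float) -> "CompetitionMixture":
        return CompetitionMixture(self.a_total, p_total, self.w_total, self.kp, self.kw)


@dataclass(frozen=True)
class SpeciesState:
    """Free and bound species concentrations at equilibrium (molar)."""

    a_free: float
    p_free: float
    w_free: float
    pa: float
    wa: float

    @property
    def a_total(self) -> float:
        return self.a_free + self.pa + self.wa

    @property
    def p_total(self) -> float:
        return self.p_free + self.pa

    @property
    def w_total(self) -> float:
        return self.w_free + self.wa


@dataclass(frozen=True)
class AnisotropyEndpoints:
    """Anisotropy of the free and fully actin-bound probe."""

    r_free: float
    r_bound: float

    def __post_init__(self):
        if self.r_bound == self.r_free:
            raise InvalidInputError("r_bound must differ from r_free")


@dataclass(frozen=True)
class QuenchEndpoints:
    """Fluorescence intensities of the free and bound labeled species."""

    i_free: float
    i_bound: float

    def __post_init__(self):
        if self.i_bound == self.i_free:
            raise InvalidInputError("i_bound must differ from i_free")


@dataclass
class TitrationSeries:
    """A titration: total titrant concentrations vs. measured signal."""

    titrant_total: np.ndarray
    signal: np.ndarray
    signal_err: Optional[np.ndarray] = None

    def __post_init__(self):
        self.titrant_total = np.asarray(self.titrant_total, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal_err is not None:
            self.signal_err = np.asarray(self.signal_err, dtype=float)
        n = self.titrant_total.size
        if n < 4 or self.signal.size != n:
            raise InvalidInputError("titration needs >= 4 matched points")
        if self.signal_err is not None and self.signal_err.size != n:
            raise InvalidInputError("signal_err length mismatch")
        if np.any(self.titrant_total < 0):
            raise InvalidInputError("titrant concentrations must be >= 0")
        # sort by titrant; duplicates are treated as replicates
        order = np.argsort(self.titrant_total, kind="stable")
        self.titrant_total = self.titrant_total[order]
        self.signal = self.signal[order]
        if self.signal_err is not None:
            self.signal_err = self.signal_err[order]


@dataclass
class CompetitionFit:
    """Result of a competition-titration fit."""

    kp: AffinityConstant
    ends: AnisotropyEndpoints
    ends_err: tuple
    result: lmfit.minimizer.MinimizerResult = field(repr=False)


@dataclass
class QuenchFit:
    """Result of a quadratic-isotherm quench fit."""

    kd: AffinityConstant
    ends: QuenchEndpoints
    ends_err: tuple
    result: lmfit.minimizer.MinimizerResult = field(repr=False)


# --------------------------------------------------------------------------
# competition solver
# --------------------------------------------------------------------------

def _species_from_a_free(mix: CompetitionMixture, a_free: float) -> SpeciesState:
    pa = mix.p_total * a_free / (mix.kp.kd + a_free)
    wa = mix.w_total * a_free / (mix.kw.kd + a_free)
    return SpeciesState(
        a_free=a_free,
        p_free=mix.p_total - pa,
        w_free=mix.w_total - wa,
        pa=pa,
        wa=wa,
    )


def _a_free_bisection(mix: CompetitionMixture) -> float:
    """Free-actin root of the conservation equation by bracketed root-finding."""

    def excess(a_free):
        return (
            a_free
            + mix.p_total * a_free / (mix.kp.kd + a_free)
            + mix.w_total * a_free / (mix.kw.kd + a_free)
            - mix.a_total
        )

    if mix.a_total == 0.0:
        return 0.0
    # excess is strictly increasing in a_free, negative at 0, positive at a_total
    return brentq(excess, 0.0, mix.a_total, xtol=1e-300, rtol=8.881784197001252e-16)


def _a_free_trigonometric(mix: CompetitionMixture, clamp_tol: float = 1e-9) -> float:
    """Closed-form free actin from the cubic in trigonometric form.

    The conservation/mass-action system reduces to a depressed cubic whose
    unique physical root is expressed through ``arccos``; the argument is
    clamped when floating-point noise pushes it marginally outside [-1, 1].
    """
    kp, kw = mix.kp.kd, mix.kw.kd
    a0, p0, w0 = mix.a_total, mix.p_total, mix.w_total
    a = kp + kw + p0 + w0 - a0
    b = kp * (w0 - a0) + kw * (p0 - a0) + kp * kw
    c = -kp * kw * a0
    disc = a * a - 3.0 * b
    if disc <= 0.0:
        raise FloatingPointError("degenerate cubic discriminant")
    arg = (-2.0 * a ** 3 + 9.0 * a * b - 27.0 * c) / (2.0 * np.sqrt(disc ** 3))
    if abs(arg) > 1.0:
        if abs(arg) - 1.0 > clamp_tol:
            raise FloatingPointError("arccos argument out of range")
        arg = np.clip(arg, -1.0, 1.0)
    theta = np.arccos(arg)
    root = (2.0 * np.sqrt(disc) * np.cos(theta / 3.0) - a) / 3.0
    # Newton polish on the conservation equation: the trigonometric form
    # loses ~half the mantissa by cancellation when free actin is many
    # orders below the totals
    kp_, kw_ = mix.kp.kd, mix.kw.kd
    for _ in range(3):
        if root <= 0.0:
            break
        g = root * (1.0 + p0 / (kp_ + root) + w0 / (kw_ + root)) - a0
        dg = 1.0 + p0 * kp_ / (kp_ + root) ** 2 + w0 * kw_ / (kw_ + root) ** 2
        step = g / dg
        if abs(step) <= 1e-15 * root:
            break
        root -= step
    return root


def _state_residual(mix: CompetitionMixture, st: SpeciesState) -> float:
    """Worst relative conservation / mass-action violation of a candidate state."""
    scale_a = max(mix.a_total, 1e-300)
    res = abs(st.a_free + st.pa + st.wa - mix.a_total) / scale_a
    res = max(res, abs(st.p_free + st.pa - mix.p_total) / max(mix.p_total, scale_a))
    res = max(res, abs(st.w_free + st.wa - mix.w_total) / max(mix.w_total, scale_a))
    if st.pa > 0:
        res = max(res, abs(st.pa * mix.kp.kd - st.a_free * st.p_free) / (st.pa * mix.kp.kd))
    if st.wa > 0:
        res = max(res, abs(st.wa * mix.kw.kd - st.a_free * st.w_free) / (st.wa * mix.kw.kd))
    return res


def solve_two_ligand_competition(
    mix: CompetitionMixture,
    method: str = "auto",
    mass_action_rtol: float = 1e-8,
) -> SpeciesState:
    """Equilibrium species of the two-ligand competition for actin monomers.

    Parameters
    ----------
    mix
        Total concentrations and the two dissociation constants.
    method
        ``"auto"`` (closed form, falling back to bisection when the
        trigonometric expression is ill-conditioned), ``"closed"``, or
        ``"bisection"``.
    mass_action_rtol
        Acceptance tolerance on conservation and mass action; exceeding it
        after both routes raises :class:`ConvergenceError`.
    """
    if method not in ("auto", "closed", "bisection"):
        raise InvalidInputError(f"unknown method {method!r}")

    if mix.a_total == 0.0:
        return SpeciesState(0.0, mix.p_total, mix.w_total, 0.0, 0.0)
    if mix.p_total == 0.0 and mix.w_total == 0.0:
        return SpeciesState(mix.a_total, 0.0, 0.0, 0.0, 0.0)

    candidates = []
    if method in ("auto", "closed"):
        try:
            a_free = _a_free_trigonometric(mix)
            if 0.0 <= a_free <= mix.a_total:
                candidates.append(_species_from_a_free(mix, a_free))
        except FloatingPointError:
            if method == "closed":
                raise ConvergenceError("closed-form solution is degenerate")
    if method in ("auto", "bisection") and not candidates:
        candidates.append(_species_from_a_free(mix, _a_free_bisection(mix)))

    st = candidates[0]
    if _state_residual(mix, st) > mass_action_rtol:
        if method == "auto":  # closed form was inaccurate; re-solve numerically
            st = _species_from_a_free(mix, _a_free_bisection(mix))
        if _state_residual(mix, st) > mass_action_rtol:
            raise ConvergenceError(
                "equilibrium solution violates mass action beyond tolerance"
            )
    return st


def predict_anisotropy(
    state: SpeciesState,
    ends: AnisotropyEndpoints,
    w_total: float,
    mode: str = "bound_fraction",
) -> float:
    """Anisotropy of the probe given an equilibrium state.

    ``mode="bound_fraction"`` (default) is linear in the bound-probe
    fraction, ``r = r_f + (r_b - r_f) * wa / w_total``, which keeps the
    observable dimensionless.  ``mode="printed"`` reproduces the literal
    published expression, linear in the profilin-actin concentration, for
    audit purposes.
    """
    if w_total <= 0:
        raise InvalidInputError("w_total must be > 0")
    if mode == "bound_fraction":
        return ends.r_free + (ends.r_bound - ends.r_free) * state.wa / w_total
    if mode == "printed":
        return ends.r_free + (ends.r_bound - ends.r_free) * state.pa
    raise InvalidInputError(f"unknown mode {mode!r}")


def fit_competition_affinity(
    series: TitrationSeries,
    mix_template: CompetitionMixture,
    ends_guess: AnisotropyEndpoints,
    vary_endpoints: bool = True,
) -> CompetitionFit:
    """Fit the competitor affinity ``kp`` from an anisotropy titration.

    The titrant is the competitor (profilin); the probe affinity ``kw`` is
    known and held fixed.  The model nests the exact competition solver
    inside the least-squares objective.  Unweighted unless ``signal_err``
    is present, in which case inverse-variance weights are used.
    """
    if np.ptp(series.signal) == 0:
        warnings.warn("flat titration: kp is unidentifiable", IdentifiabilityWarning)

    params = lmfit.Parameters()
    params.add("log10_kp", value=np.log10(mix_template.kp.kd), min=-13.0, max=-2.0)
    params.add("r_free", value=ends_guess.r_free, vary=vary_endpoints)
    params.add("r_bound", value=ends_guess.r_bound, vary=vary_endpoints)

    conc = series.titrant_total
    weights = None if series.signal_err is None else 1.0 / series.signal_err

    def residual(p):
        kp = AffinityConstant(10.0 ** p["log10_kp"].value)
        model = np.empty_like(conc)
        for i, p_tot in enumerate(conc):
            mix = CompetitionMixture(
                mix_template.a_total, p_tot, mix_template.w_total, kp, mix_template.kw
            )
            st = solve_two_ligand_competition(mix)
            # inline the bound-fraction signal: the optimizer may pass
            # transiently degenerate endpoints the dataclass would reject
            model[i] = p["r_free"].value + (
                p["r_bound"].value - p["r_free"].value
            ) * st.wa / mix_template.w_total
        r = model - series.signal
        return r if weights is None else r * weights

    out = lmfit.minimize(residual, params, method="leastsq")
    if not out.success:
        raise FitError(f"competition fit did not converge: {out.message}")
    kp_val = 10.0 ** out.params["log10_kp"].value
    # delta method: sigma_kp = ln(10) * kp * sigma_log10
    log_err = out.params["log10_kp"].stderr
    kp_err = np.log(10.0) * kp_val * log_err if log_err is not None else None
    if out.params["r_free"].value == out.params["r_bound"].value:
        raise FitError("fitted endpoints collapsed: titration carries no binding signal")
    ends = AnisotropyEndpoints(out.params["r_free"].value, out.params["r_bound"].value)
    ends_err = (out.params["r_free"].stderr, out.params["r_bound"].stderr)
    return CompetitionFit(AffinityConstant(kp_val, kp_err), ends, ends_err, out)


# --------------------------------------------------------------------------
# quadratic (ligand-depletion) binding isotherm
# --------------------------------------------------------------------------

def _quadratic_complex(a_total, t_total, kd):
    """Bound-complex concentration from the ligand-depletion quadratic."""
    s = kd + a_total + t_total
    disc = s * s - 4.0 * a_total * t_total
    if np.any(disc < 0):
        raise FloatingPointError("negative discriminant in quadratic isotherm")
    return 0.5 * (s - np.sqrt(disc))


def predict_quench(
    a_total: float,
    t_total,
    kd: AffinityConstant,
    ends: QuenchEndpoints,
    normalization: str = "titrant",
) -> np.ndarray:
    """Fluorescence intensity of a quench titration under ligand depletion.

    ``normalization="titrant"`` evaluates the published expression exactly
    (bound-complex root divided by the total titrant concentration);
    ``normalization="actin"`` divides by the labeled-actin total instead,
    so the signal tracks the bound fraction of the fluorescent species and
    remains defined at zero titrant.
    """
    t = np.asarray(t_total, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    if not np.all(np.isfinite(t)) or np.any(t < 0):
        raise InvalidInputError("t_total must be finite and >= 0")
    if normalization == "titrant":
        if np.any(t == 0):
            raise InvalidInputError(
                "titrant normalization is undefined at t_total = 0; "
                "use normalization='actin'"
            )
        denom = t
    elif normalization == "actin":
        if a_total <= 0:
            raise InvalidInputError("a_total must be > 0 for actin normalization")
        denom = np.full_like(t, a_total)
    else:
        raise InvalidInputError(f"unknown normalization {normalization!r}")
    complex_conc = _quadratic_complex(a_total, t, kd.kd if isinstance(kd, AffinityConstant) else kd)
    bound = complex_conc / denom
    out = ends.i_free + (ends.i_bound - ends.i_free) * bound
    return out.item() if scalar else out


def fit_quench_affinity(
    series: TitrationSeries,
    a_total: float,
    normalization: str = "actin",
) -> QuenchFit:
    """Fit ``kd`` and intensity endpoints from a quench titration.

    Defaults to the actin-normalized isotherm so titrations that start at
    zero titrant (the full published design) can be fitted directly.
    """
    if np.ptp(series.signal) == 0:
        warnings.warn("flat titration: kd is unidentifiable", IdentifiabilityWarning)

    t = series.titrant_total
    sig = series.signal
    weights = None if series.signal_err is None else 1.0 / series.signal_err

    # endpoint guesses from the titration extremes; kd from mid-signal crossing
    i_free0, i_bound0 = sig[0], sig[-1]
    if i_free0 == i_bound0:
        i_bound0 = i_free0 + (1.0 if np.ptp(sig) == 0 else np.ptp(sig))
    half = 0.5 * (i_free0 + i_bound0)
    kd0 = max(t[np.argmin(np.abs(sig - half))], 1e-9)

    params = lmfit.Parameters()
    params.add("log10_kd", value=np.log10(kd0), min=-13.0, max=0.0)
    params.add("i_free", value=i_free0)
    params.add("i_bound", value=i_bound0)

    def residual(p):
        ends = QuenchEndpoints(p["i_free"].value, p["i_bound"].value)
        model = predict_quench(
            a_total, t, AffinityConstant(10.0 ** p["log10_kd"].value), ends,
            normalization=normalization,
        )
        r = model - sig
        return r if weights is None else r * weights

    out = lmfit.minimize(residual, params, method="leastsq")
    if not out.success:
        raise FitError(f"quench fit did not converge: {out.message}")
    kd_val = 10.0 ** out.params["log10_kd"].value
    log_err = out.params["log10_kd"].stderr
    kd_err = np.log(10.0) * kd_val * log_err if log_err is not None else None
    ends = QuenchEndpoints(out.params["i_free"].value, out.params["i_bound"].value)
    ends_err = (out.params["i_free"].stderr, out.params["i_bound"].stderr)
    return QuenchFit(AffinityConstant(kd_val, kd_err), ends, ends_err, out)


# --------------------------------------------------------------------------
# assay-design tables
# --------------------------------------------------------------------------

def free_species_table(conditions: Iterable[CompetitionMixture]) -> pd.DataFrame:
    """Equilibrium species for a list of assay mixes, one row per condition.

    Used to verify assay designs, e.g. that adding free profilin or
    thymosin-beta4 as a nucleation suppressant leaves the profilin-actin
    complex as the dominant actin-bound pool.
    """
    rows = []
    for mix in conditions:
        st = solve_two_ligand_competition(mix)
        rows.append(
            {
                "a_total": mix.a_total,
                "p_total": mix.p_total,
                "w_total": mix.w_total,
                "a_free": st.a_free,
                "p_free": st.p_free,
                "w_free": st.w_free,
                "pa": st.pa,
                "wa": st.wa,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["a_total", "p_total", "w_total", "a_free", "p_free", "w_free", "pa", "wa"],
    )
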