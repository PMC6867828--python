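"""Stopped-flow pseudo-first-order analysis of profilin-actin association.

Tryptophan-quench traces recorded after mixing excess profilin with a
fixed actin-monomer concentration relax as a single exponential whose
observed rate is linear in the titrant concentration,
``k_obs = k_on * [P] + k_off``.  Trace fitting, the association-rate
regression and the dissociation rate computed from the equilibrium
constant (``k_off = K_D * k_on``, with first-order error propagation)
live here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import lmfit
import numpy as np
from scipy import stats

from .equilibria import AffinityConstant
from .errors import DataQualityWarning, FitError, InvalidInputError

__all__ = [
    "StoppedFlowTrace",
    "PseudoFirstOrderResult",
    "AssociationRate",
    "RateConstants",
    "fit_single_exponential",
    "fit_association_rate",
    "dissociation_rate",
]


@dataclass
class StoppedFlowTrace:
    """One stopped-flow record: intensity vs. time at one profilin total."""

    time: np.ndarray
    intensity: np.ndarray
    profilin_total: float

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.time.size < 10 or self.intensity.size != self.time.size:
            raise InvalidInputError("trace needs >= 10 matched points")
        if self.time[0] < 0 or np.any(np.diff(self.time) <= 0):
            raise InvalidInputError("time must be strictly increasing and start >= 0")
        if self.profilin_total < 0:
            raise InvalidInputError("profilin_total must be >= 0")


@dataclass
class PseudoFirstOrderResult:
    """Observed relaxation rate of one trace with fitted amplitudes."""

    k_obs: float
    k_obs_err: Optional[float]
    i_free: float
    i_bound: float
    profilin_total: Optional[float] = None
    result: Optional[lmfit.minimizer.MinimizerResult] = field(default=None, repr=False)

    def __post_init__(self):
        if self.k_obs <= 0:
            raise InvalidInputError("k_obs must be > 0")


@dataclass
class AssociationRate:
    """Slope (k_on) and intercept of the k_obs vs. concentration regression."""

    k_on: float
    k_on_err: float
    intercept: float
    intercept_err: float
    r_squared: float


@dataclass
class RateConstants:
    """Association/dissociation rate constants tied to an affinity."""

    k_on: float
    k_off: float
    kd: AffinityConstant
    k_on_err: Optional[float] = None
    k_off_err: Optional[float] = None

    def __post_init__(self):
        if self.k_on <= 0 or self.k_off <= 0:
            raise InvalidInputError("rate constants must be > 0")


def fit_single_exponential(
    trace: StoppedFlowTrace,
    fit_t0: bool = False,
    fit_drift: bool = False,
    actin_total: Optional[float] = None,
) -> PseudoFirstOrderResult:
    """Fit ``I(t) = (I_f - I_b) exp(-k_obs t) + I_b`` to one trace.

    Initial guesses come from the trace endpoints and a log-linearised
    slope.  ``fit_t0`` adds a time-origin offset, ``fit_drift`` a linear
    baseline (both off by default).  Passing the actin concentration as
    ``actin_total`` enables a pseudo-first-order validity warning when the
    titrant is not in at least tenfold excess.
    """
    t, y = trace.time, trace.intensity
    if np.ptp(y) == 0:
        raise FitError("flat trace: no relaxation to fit")
    if actin_total is not None and trace.profilin_total < 10.0 * actin_total:
        warnings.warn(
            "profilin is not in >= 10x excess over actin; the pseudo-first-order "
            "single-exponential model may be inaccurate",
            DataQualityWarning,
        )

    i_b0, i_f0 = y[-1], y[0]
    amp = y - i_b0
    # log-linear slope on the early part of the decay, guarding sign/zeros
    mask = np.abs(amp) > 0.05 * np.abs(i_f0 - i_b0)
    if mask.sum() >= 2:
        k0 = max(-stats.linregress(t[mask], np.log(np.abs(amp[mask]))).slope, 1e-6)
    else:
        k0 = 1.0 / max(t[-1] - t[0], 1e-12)

    params = lmfit.Parameters()
    params.add("k_obs", value=k0, min=1e-12)
    params.add("i_free", value=i_f0)
    params.add("i_bound", value=i_b0)
    params.add("t0", value=t[0], vary=fit_t0)
    params.add("drift", value=0.0, vary=fit_drift)

    def residual(p):
        model = (p["i_free"] - p["i_bound"]) * np.exp(
            -p["k_obs"] * (t - p["t0"])
        ) + p["i_bound"] + p["drift"] * (t - p["t0"])
        return model - y

    out = lmfit.minimize(residual, params, method="leastsq")
    if not out.success:
        raise FitError(f"exponential fit did not converge: {out.message}")
    k = out.params["k_obs"].value
    if k <= 1e-10:
        raise FitError("fitted k_obs is not positive; trace may be non-exponential")
    span = k * (t[-1] - t[0])
    if span < 3.0:
        warnings.warn(
            f"trace spans only {span:.2f} e-folding times (< 3); "
            "k_obs may be poorly determined",
            DataQualityWarning,
        )
    return PseudoFirstOrderResult(
        k_obs=k,
        k_obs_err=out.params["k_obs"].stderr,
        i_free=out.params["i_free"].value,
        i_bound=out.params["i_bound"].value,
        profilin_total=trace.profilin_total,
        result=out,
    )


def fit_association_rate(
    results: Sequence[PseudoFirstOrderResult],
    concentrations: Optional[Sequence[float]] = None,
) -> AssociationRate:
    """k_on from linear regression of k_obs against the titrant total.

    The intercept is estimated rather than pinned at zero: under the
    relaxation model it equals k_off and serves as an independent check.
    """
    if concentrations is None:
        concentrations = [r.profilin_total for r in results]
        if any(c is None for c in concentrations):
            raise InvalidInputError("results lack profilin_total; pass concentrations")
    conc = np.asarray(concentrations, dtype=float)
    k_obs = np.asarray([r.k_obs for r in results], dtype=float)
    if conc.size != k_obs.size:
        raise InvalidInputError("concentrations/results length mismatch")
    if np.unique(conc).size < 3:
        raise InvalidInputError("need >= 3 distinct concentrations")
    reg = stats.linregress(conc, k_obs)
    if reg.slope <= 0:
        raise FitError("non-physical (non-positive) association-rate slope")
    return AssociationRate(
        k_on=reg.slope,
        k_on_err=reg.stderr,
        intercept=reg.intercept,
        intercept_err=reg.intercept_stderr,
        r_squared=reg.rvalue ** 2,
    )


def dissociation_rate(
    kd: AffinityConstant,
    k_on: float,
    k_on_err: Optional[float] = None,
) -> RateConstants:
    """``k_off = K_D * k_on`` with first-order Gaussian error propagation.

    ``sigma_koff = sqrt((k_on * sigma_kd)^2 + (kd * sigma_kon)^2)``; the
    error is omitted when either input error is unavailable.
    """
    if k_on <= 0:
        raise InvalidInputError("k_on must be > 0")
    k_off = kd.kd * k_on
    k_off_err = None
    if kd.kd_err is not None and k_on_err is not None:
        k_off_err = float(np.hypot(k_on * kd.kd_err, kd.kd * k_on_err))
    return RateConstants(
        k_on=k_on, k_off=k_off, kd=kd, k_on_err=k_on_err, k_off_err=k_off_err
    )
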