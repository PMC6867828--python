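"""The elongation-cycle model of actin filament growth from profilin-actin.

Barbed-end growth from profilin-actin is a repeating three-reaction cycle:

1. a profilin-actin complex binds the free barbed end (second order,
   ``k_bind``, the only concentration-dependent step),
2. the incorporated monomer undergoes its structural monomer-to-filament
   transition (first order, ``k_trans``),
3. profilin is released from the terminal protomer (first order,
   ``k_release``), regenerating a free end.

Because the steps are sequential, the steady-state velocity is the
harmonic sum ``v(c) = [1/(k_bind c) + 1/k_trans + 1/k_release]^-1`` —
exactly a hyperbola ``v_max c / (K_0.5 + c)`` with
``v_max = (1/k_trans + 1/k_release)^-1`` and ``K_0.5 = v_max / k_bind``.
At saturating profilin-actin the cycle is limited by profilin release, so
growth is buffered against changes in the soluble subunit concentration.
Formin polymerases accelerate reactions 1 (via FH1-mediated delivery) and
3 (via the end-bound FH2 domain), raising both the low-concentration
slope and the plateau.

The module also provides an exact-event stochastic simulator of single
filaments (cycle mode and bare-actin birth-death mode), kymograph-style
velocity estimation, and the hyperbolic / low-concentration-linear fits
used for measured velocity curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import lmfit
import numpy as np
from scipy import stats

from .errors import (
    FitError,
    IdentifiabilityWarning,
    InvalidInputError,
    TrajectoryTruncatedError,
)
from .units import RISE_PER_SUBUNIT_NM, subunits_per_s_to_um_per_s

__all__ = [
    "CycleRates",
    "ForminFactors",
    "BareActinRates",
    "VelocityCurve",
    "HyperbolicFit",
    "LinearFit",
    "FilamentTrajectory",
    "END_FREE",
    "END_CAPPED_PRE",
    "END_CAPPED_POST",
    "cycle_velocity",
    "hyperbolic_params_from_cycle",
    "apply_formin",
    "relative_enhancement",
    "simulate_filament",
    "simulate_bare_filament",
    "estimate_trajectory_velocity",
    "fit_hyperbolic",
    "fit_linear_regime",
    "buffering_ratio",
]

#: end-occupancy codes recorded per event
END_FREE = 0  # free barbed end, awaiting profilin-actin
END_CAPPED_PRE = 1  # profilin-capped, monomer not yet in filament conformation
END_CAPPED_POST = 2  # profilin-capped, transition done, awaiting release


@dataclass(frozen=True)
class CycleRates:
    """Microscopic rate constants of the three-reaction elongation cycle."""

    k_bind: float  # M^-1 s^-1, reaction 1
    k_trans: float  # s^-1, reaction 2
    k_release: float  # s^-1, reaction 3

    def __post_init__(self):
        for name in ("k_bind", "k_trans", "k_release"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise InvalidInputError(f"{name} must be positive and finite, got {v}")


@dataclass(frozen=True)
class ForminFactors:
    """Multiplicative formin accelerations of reactions 1 and 3."""

    f_bind: float
    f_release: float
    label: str = ""

    def __post_init__(self):
        if self.f_bind < 1 or self.f_release < 1:
            raise InvalidInputError("formin factors must be >= 1")


@dataclass(frozen=True)
class BareActinRates:
    """Association/dissociation rate constants of profilin-free monomers."""

    k_plus: float  # M^-1 s^-1
    k_minus: float  # s^-1

    def __post_init__(self):
        if self.k_plus <= 0 or self.k_minus < 0:
            raise InvalidInputError("k_plus must be > 0 and k_minus >= 0")


@dataclass
class VelocityCurve:
    """Mean per-filament velocity vs. total profilin-actin concentration."""

    conc: np.ndarray  # molar
    v_mean: np.ndarray  # subunits / s
    v_sd: np.ndarray
    n: np.ndarray  # filaments per condition

    def __post_init__(self):
        self.conc = np.asarray(self.conc, dtype=float)
        self.v_mean = np.asarray(self.v_mean, dtype=float)
        self.v_sd = np.asarray(self.v_sd, dtype=float)
        self.n = np.asarray(self.n, dtype=int)
        m = self.conc.size
        if any(a.size != m for a in (self.v_mean, self.v_sd, self.n)):
            raise InvalidInputError("curve arrays must have equal length")
        if np.any(self.conc < 0) or np.any(self.n < 1):
            raise InvalidInputError("conc must be >= 0 and n >= 1")


@dataclass(frozen=True)
class HyperbolicFit:
    """Saturation-law parameters ``v = v_max c / (K_0.5 + c)``."""

    v_max: float
    k_half: float
    v_max_err: Optional[float] = None
    k_half_err: Optional[float] = None

    def __post_init__(self):
        if self.v_max <= 0 or self.k_half <= 0:
            raise InvalidInputError("v_max and k_half must be > 0")

    def velocity(self, conc):
        """Model velocity at concentration(s) ``conc`` (molar)."""
        c = np.asarray(conc, dtype=float)
        return self.v_max * c / (self.k_half + c)


@dataclass(frozen=True)
class LinearFit:
    """Low-concentration linear regime: slope (apparent k_bind) + intercept."""

    slope: float
    intercept: float
    slope_err: float
    intercept_err: float
    n_points: int


@dataclass
class FilamentTrajectory:
    """Event record of one simulated barbed end."""

    times: np.ndarray  # event times, s
    lengths: np.ndarray  # filament length after each event, subunits
    end_state: np.ndarray  # END_* code after each event
    seed: Optional[int]
    params: dict

    @property
    def duration(self) -> float:
        return float(self.times[-1]) if self.times.size else 0.0


# --------------------------------------------------------------------------
# analytic cycle model
# --------------------------------------------------------------------------

def cycle_velocity(rates: CycleRates, conc) -> np.ndarray:
    """Steady-state elongation velocity of the cycle at concentration ``conc``.

    Harmonic sum of the three mean step durations; zero at zero
    concentration, saturating at ``(1/k_trans + 1/k_release)^-1``.
    """
    c = np.asarray(conc, dtype=float)
    if np.any(c < 0):
        raise InvalidInputError("conc must be >= 0")
    tau_sat = 1.0 / rates.k_trans + 1.0 / rates.k_release
    with np.errstate(divide="ignore"):
        v = np.where(c > 0, 1.0 / (1.0 / (rates.k_bind * c) + tau_sat), 0.0)
    return v.item() if np.ndim(conc) == 0 else v


def hyperbolic_params_from_cycle(rates: CycleRates) -> HyperbolicFit:
    """Exact (v_max, K_0.5) of the cycle's hyperbolic velocity law."""
    v_max = 1.0 / (1.0 / rates.k_trans + 1.0 / rates.k_release)
    return HyperbolicFit(v_max=v_max, k_half=v_max / rates.k_bind)


def apply_formin(rates: CycleRates, factors: ForminFactors) -> CycleRates:
    """Cycle rates of a formin-bound end: reactions 1 and 3 accelerated."""
    return CycleRates(
        k_bind=rates.k_bind * factors.f_bind,
        k_trans=rates.k_trans,
        k_release=rates.k_release * factors.f_release,
    )


def relative_enhancement(rates: CycleRates, factors: ForminFactors, conc) -> np.ndarray:
    """Formin/free velocity ratio at concentration ``conc``.

    Decreases monotonically from ``f_bind`` (binding-limited regime) toward
    the v_max ratio (release-limited regime) as concentration rises; at
    ``conc == 0`` the binding-limited limit ``f_bind`` is returned.
    """
    c = np.asarray(conc, dtype=float)
    if np.any(c < 0):
        raise InvalidInputError("conc must be >= 0")
    accelerated = apply_formin(rates, factors)
    with np.errstate(invalid="ignore"):
        ratio = np.where(
            c > 0,
            np.divide(
                cycle_velocity(accelerated, np.where(c > 0, c, 1.0)),
                cycle_velocity(rates, np.where(c > 0, c, 1.0)),
            ),
            factors.f_bind,
        )
    return ratio.item() if np.ndim(conc) == 0 else ratio


# --------------------------------------------------------------------------
# stochastic single-filament simulation
# --------------------------------------------------------------------------

def simulate_filament(
    rates: CycleRates,
    conc: float,
    duration: float,
    seed,
    start_length: int = 0,
    event_cap: int = 10_000_000,
) -> FilamentTrajectory:
    """Exact-event stochastic realization of the elongation cycle.

    The end walks E -> (k_bind c) -> capped-pre -> (k_trans) ->
    capped-post -> (k_release) -> E; the length increments at the binding
    event (subunit incorporation) while end occupancy is tracked
    separately.  Waiting times are exponential, so whole cycles can be
    drawn in vectorized batches without approximation.
    """
    if duration <= 0:
        raise InvalidInputError("duration must be > 0")
    if conc < 0:
        raise InvalidInputError("conc must be >= 0")
    params = {
        "mode": "cycle",
        "conc": conc,
        "k_bind": rates.k_bind,
        "k_trans": rates.k_trans,
        "k_release": rates.k_release,
    }
    rng = np.random.default_rng(seed)
    if conc == 0.0:
        return FilamentTrajectory(
            np.empty(0), np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int8),
            seed=_seed_repr(seed), params=params,
        )

    means = np.array([1.0 / (rates.k_bind * conc), 1.0 / rates.k_trans, 1.0 / rates.k_release])
    tau = means.sum()
    times_chunks, total_time, total_cycles = [], 0.0, 0

    while total_time < duration:
        expect = max((duration - total_time) / tau, 1.0)
        n = int(expect + 10.0 * np.sqrt(expect) + 16)
        if (total_cycles + n) * 3 > event_cap:
            n = max(event_cap // 3 - total_cycles, 0)
            if n == 0:
                traj = _assemble_cycle_trajectory(
                    times_chunks, duration, start_length, seed, params, truncated=True
                )
                raise TrajectoryTruncatedError(
                    f"event cap {event_cap} reached before t={duration}", trajectory=traj
                )
        waits = rng.exponential(means, size=(n, 3))  # one row per cycle
        times_chunks.append(total_time + waits.reshape(-1).cumsum())
        total_time = times_chunks[-1][-1]
        total_cycles += n

    return _assemble_cycle_trajectory(times_chunks, duration, start_length, seed, params)


def _assemble_cycle_trajectory(times_chunks, duration, start_length, seed, params,
                               truncated=False):
    times = np.concatenate(times_chunks) if times_chunks else np.empty(0)
    times = times[times <= duration]
    n_ev = times.size
    # events repeat (bind, trans, release); length rises at the bind events
    phase = np.arange(n_ev) % 3
    lengths = start_length + np.cumsum(phase == 0)
    end_state = np.choose(phase, [END_CAPPED_PRE, END_CAPPED_POST, END_FREE]).astype(np.int8)
    return FilamentTrajectory(
        times=times,
        lengths=lengths.astype(np.int64),
        end_state=end_state,
        seed=_seed_repr(seed),
        params=dict(params, truncated=truncated, start_length=start_length),
    )


def simulate_bare_filament(
    rates: BareActinRates,
    conc: float,
    duration: float,
    seed,
    start_length: int = 0,
    event_cap: int = 10_000_000,
) -> FilamentTrajectory:
    """Birth-death simulation of a bare (profilin-free) barbed end.

    Gain rate ``k_plus * conc``, loss rate ``k_minus``; the length is
    floored at zero (a bare seed cannot shrink below the surface anchor),
    where only gain events can occur.  Events are drawn in vectorized
    stretches between boundary visits, which keeps the realization exact.
    """
    if duration <= 0:
        raise InvalidInputError("duration must be > 0")
    if conc < 0:
        raise InvalidInputError("conc must be >= 0")
    rng = np.random.default_rng(seed)
    k_gain = rates.k_plus * conc
    k_loss = rates.k_minus
    params = {"mode": "bare", "conc": conc, "k_plus": rates.k_plus, "k_minus": rates.k_minus}

    times, steps = [], []
    t, length, n_total = 0.0, int(start_length), 0
    while t < duration:
        if n_total >= event_cap:
            traj = _assemble_bare_trajectory(times, steps, start_length, seed, params, True)
            raise TrajectoryTruncatedError(
                f"event cap {event_cap} reached before t={duration}", trajectory=traj
            )
        if length == 0:
            if k_gain == 0.0:
                break  # absorbing: nothing can ever happen again
            t = t + rng.exponential(1.0 / k_gain)
            if t > duration:
                break
            length = 1
            times.append(np.array([t]))
            steps.append(np.array([1], dtype=np.int64))
            n_total += 1
            continue
        # away from the boundary both moves are available at constant rates
        total = k_gain + k_loss
        expect = max((duration - t) * total, 1.0)
        n = int(min(expect + 10.0 * np.sqrt(expect) + 16, event_cap - n_total))
        wt = rng.exponential(1.0 / total, size=n)
        st = np.where(rng.random(n) < k_gain / total, 1, -1).astype(np.int64)
        ct = t + np.cumsum(wt)
        lengths = length + np.cumsum(st)
        # stop this stretch at the first boundary hit or past-duration event
        hit_zero = np.nonzero(lengths == 0)[0]
        stop = hit_zero[0] + 1 if hit_zero.size else n
        over = np.searchsorted(ct[:stop], duration, side="right")
        stop = min(stop, over)
        times.append(ct[:stop])
        steps.append(st[:stop])
        n_total += stop
        if stop == 0:
            break
        t = ct[stop - 1]
        length = int(lengths[stop - 1])
        if over < (hit_zero[0] + 1 if hit_zero.size else n):
            break  # duration reached before the boundary
    return _assemble_bare_trajectory(times, steps, start_length, seed, params)


def _assemble_bare_trajectory(times, steps, start_length, seed, params, truncated=False):
    if times:
        t = np.concatenate(times)
        s = np.concatenate(steps)
    else:
        t = np.empty(0)
        s = np.empty(0, dtype=np.int64)
    lengths = start_length + np.cumsum(s)
    end_state = np.zeros(t.size, dtype=np.int8)
    return FilamentTrajectory(
        times=t, lengths=lengths, end_state=end_state,
        seed=_seed_repr(seed),
        params=dict(params, truncated=truncated, start_length=start_length),
    )


def _seed_repr(seed):
    """Store a JSON-friendly representation of whatever seeded the run."""
    if seed is None or isinstance(seed, int):
        return seed
    return repr(seed)


# --------------------------------------------------------------------------
# velocity estimation and curve fitting
# --------------------------------------------------------------------------

def estimate_trajectory_velocity(traj: FilamentTrajectory, unit: str = "subunits_per_s"):
    """Least-squares slope of length vs. time, mirroring kymograph analysis.

    Includes the initial point (t=0, start length).  Returns
    ``(velocity, stderr)`` in subunits/s or um/s (2.7 nm per subunit).
    """
    if traj.times.size < 2:
        raise InvalidInputError("trajectory needs >= 2 events for a slope")
    start = traj.params.get("start_length", 0)
    t = np.concatenate(([0.0], traj.times))
    ln = np.concatenate(([start], traj.lengths)).astype(float)
    reg = stats.linregress(t, ln)
    v, err = reg.slope, reg.stderr
    if unit == "subunits_per_s":
        return v, err
    if unit == "um_per_s":
        return subunits_per_s_to_um_per_s(v), subunits_per_s_to_um_per_s(err)
    raise InvalidInputError(f"unknown unit {unit!r}")


def fit_hyperbolic(curve: VelocityCurve, weighted: bool = False) -> HyperbolicFit:
    """Fit ``v = v_max c / (K_0.5 + c)`` to a measured velocity curve.

    Unweighted by default (curves are fitted on condition means, matching
    common practice); ``weighted=True`` uses standard errors of the means
    ``v_sd / sqrt(n)`` as weights.
    """
    c, v = curve.conc, curve.v_mean
    if c.size < 4:
        raise InvalidInputError("need >= 4 concentrations for a hyperbolic fit")
    v_max0 = float(v.max()) or 1.0
    k_half0 = float(np.interp(0.5 * v_max0, v, c, left=c[c > 0].min() if np.any(c > 0) else 1e-6))
    k_half0 = max(k_half0, 1e-9)
    if c.max() < k_half0:
        warnings.warn(
            "curve does not reach its half-saturation point; v_max and K_0.5 "
            "are weakly identified",
            IdentifiabilityWarning,
        )

    params = lmfit.Parameters()
    params.add("v_max", value=v_max0, min=1e-12)
    params.add("k_half", value=k_half0, min=1e-15)
    weights = None
    if weighted:
        sem = curve.v_sd / np.sqrt(curve.n)
        weights = np.where(sem > 0, 1.0 / np.where(sem > 0, sem, 1.0), 0.0)

    def residual(p):
        r = p["v_max"] * c / (p["k_half"] + c) - v
        return r if weights is None else r * weights

    out = lmfit.minimize(residual, params, method="leastsq")
    if not out.success:
        raise FitError(f"hyperbolic fit did not converge: {out.message}")
    return HyperbolicFit(
        v_max=out.params["v_max"].value,
        k_half=out.params["k_half"].value,
        v_max_err=out.params["v_max"].stderr,
        k_half_err=out.params["k_half"].stderr,
    )


def fit_linear_regime(curve: VelocityCurve, conc_cutoff: float) -> LinearFit:
    """Weighted linear fit to the sub-cutoff (binding-limited) points.

    The slope estimates the apparent association rate constant of
    profilin-actin for the barbed end.  Weights are inverse-variance from
    the per-condition standard errors when available.
    """
    mask = curve.conc <= conc_cutoff
    if mask.sum() < 3:
        raise InvalidInputError("need >= 3 points at or below the cutoff")
    c, v = curve.conc[mask], curve.v_mean[mask]
    sem = curve.v_sd[mask] / np.sqrt(curve.n[mask])
    if np.all(sem > 0):
        w = 1.0 / sem ** 2
    else:
        w = np.ones_like(c)
    # weighted least squares, closed form
    sw = w.sum()
    cm, vm = (w * c).sum() / sw, (w * v).sum() / sw
    sxx = (w * (c - cm) ** 2).sum()
    slope = (w * (c - cm) * (v - vm)).sum() / sxx
    intercept = vm - slope * cm
    resid = v - slope * c - intercept
    dof = max(c.size - 2, 1)
    s2 = (w * resid ** 2).sum() / dof
    slope_err = float(np.sqrt(s2 / sxx))
    intercept_err = float(np.sqrt(s2 * (1.0 / sw + cm ** 2 / sxx)))
    return LinearFit(slope, intercept, slope_err, intercept_err, int(c.size))


def buffering_ratio(fit: HyperbolicFit, c_base: float, fold: float) -> float:
    """Velocity ratio ``v(fold * c_base) / v(c_base)`` under the hyperbola.

    Quantifies how strongly elongation is buffered: near saturation the
    ratio approaches 1 even for large concentration fold-changes.
    """
    if c_base <= 0 or fold <= 0:
        raise InvalidInputError("c_base and fold must be > 0")
    return float(fit.velocity(fold * c_base) / fit.velocity(c_base))
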