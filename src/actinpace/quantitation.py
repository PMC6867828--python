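"""Cellular quantitation arithmetic.

Per-cell protein concentrations from quantitative western blots
(standard-curve inversion, molecular weight, cell count, cell volume,
and an accessible-volume fraction accounting for the endomembrane
system), lognormal cell-volume fitting, soluble/pellet fractionation
with error propagation, and Gaussian fitting of single-molecule formin
velocity distributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .elongation import HyperbolicFit, VelocityCurve, fit_hyperbolic
from .errors import DataQualityWarning, FitError, InvalidInputError

__all__ = [
    "StandardCurve",
    "BlotMeasurement",
    "CellVolumeModel",
    "ConcentrationEstimate",
    "FractionationMeasurement",
    "VelocityDistribution",
    "MW_ACTIN",
    "MW_PROFILIN",
    "fit_standard_curve",
    "concentration_per_cell",
    "fit_lognormal_volume",
    "soluble_fraction",
    "fit_gaussian_velocity",
    "velocity_vs_concentration",
]

#: default molecular weights (g/mol), overridable per measurement
MW_ACTIN = 42_000.0
MW_PROFILIN = 15_000.0

_UM3_TO_L = 1e-15  # 1 um^3 = 1e-15 L
_NG_TO_G = 1e-9


@dataclass
class StandardCurve:
    """Linear reference curve: band intensity per loaded protein mass (ng)."""

    masses: np.ndarray  # ng
    intensities: np.ndarray
    slope: float  # intensity per ng
    slope_err: float
    intercept: float
    intercept_err: float

    def mass_ng(self, intensity: float) -> float:
        """Invert intensity to mass using the slope only (intercept is QC)."""
        return intensity / self.slope


@dataclass(frozen=True)
class BlotMeasurement:
    """One background-subtracted cell-lysate band."""

    intensity: float
    n_cells: float
    protein: str = "actin"
    mw: float = MW_ACTIN

    def __post_init__(self):
        if self.intensity < 0:
            raise InvalidInputError("intensity must be >= 0")
        if self.n_cells < 1:
            raise InvalidInputError("n_cells must be >= 1")
        if self.mw <= 0:
            raise InvalidInputError("mw must be > 0")


@dataclass
class CellVolumeModel:
    """Cell-volume distribution summary (lognormal fit or known truth)."""

    mean_volume: float  # um^3
    sd_volume: float
    samples: Optional[np.ndarray] = field(default=None, repr=False)
    meanlog: Optional[float] = None
    sdlog: Optional[float] = None

    def __post_init__(self):
        if self.mean_volume <= 0 or self.sd_volume < 0:
            raise InvalidInputError("mean_volume must be > 0 and sd_volume >= 0")


@dataclass(frozen=True)
class ConcentrationEstimate:
    """Per-cell protein concentration (molar) with propagated error."""

    concentration: float
    concentration_err: Optional[float]
    accessible_volume_fraction: float = 0.5

    def __post_init__(self):
        if self.concentration < 0:
            raise InvalidInputError("concentration must be >= 0")
        if not 0 < self.accessible_volume_fraction <= 1:
            raise InvalidInputError("accessible_volume_fraction must be in (0, 1]")


@dataclass(frozen=True)
class FractionationMeasurement:
    """Supernatant/pellet band intensities plus an independent total."""

    supernatant_intensity: float
    pellet_intensity: float
    total_concentration: float  # molar
    total_concentration_err: float = 0.0
    supernatant_err: float = 0.0
    pellet_err: float = 0.0

    def __post_init__(self):
        if self.supernatant_intensity < 0 or self.pellet_intensity < 0:
            raise InvalidInputError("intensities must be >= 0")
        if self.supernatant_intensity + self.pellet_intensity == 0:
            raise InvalidInputError("supernatant and pellet cannot both be 0")


@dataclass
class VelocityDistribution:
    """Gaussian summary of single-molecule formin velocities."""

    velocities: np.ndarray
    mu: float
    mu_err: float
    sigma: float
    sigma_err: float
    n_molecules: int
    n_cells: Optional[int] = None
    unit: str = "subunits_per_s"


# --------------------------------------------------------------------------

def fit_standard_curve(masses: Sequence[float], intensities: Sequence[float]) -> StandardCurve:
    """Ordinary least-squares line through the reference titration."""
    m = np.asarray(masses, dtype=float)
    i = np.asarray(intensities, dtype=float)
    if m.size < 3 or i.size != m.size:
        raise InvalidInputError("need >= 3 matched standards")
    if np.any(m < 0) or np.any(np.diff(np.sort(m)) == 0):
        raise InvalidInputError("masses must be >= 0 and distinct")
    reg = stats.linregress(m, i)
    if reg.slope <= 0:
        raise FitError("non-positive standard-curve slope")
    return StandardCurve(
        masses=m, intensities=i,
        slope=reg.slope, slope_err=reg.stderr,
        intercept=reg.intercept, intercept_err=reg.intercept_stderr,
    )


def concentration_per_cell(
    meas: BlotMeasurement,
    curve: StandardCurve,
    vol: CellVolumeModel,
    fraction: float = 0.5,
) -> ConcentrationEstimate:
    """Per-cell concentration from band intensity, standards and cell volume.

    ``mass_per_cell = (intensity / slope) / n_cells`` (ng), then
    ``concentration = mass_per_cell / (mw * fraction * mean_volume)``.
    ``fraction`` is the accessible-volume fraction: roughly half the cell
    is endomembrane from which profilin/actin are excluded, so the default
    0.5 bounds a maximal twofold overestimate.  First-order propagation
    combines the standard-curve slope error and the volume SD.
    """
    if not 0 < fraction <= 1:
        raise InvalidInputError("fraction must be in (0, 1]")
    if curve.slope <= 0 or vol.mean_volume <= 0:
        raise InvalidInputError("slope and mean volume must be > 0")
    mass_per_cell_g = curve.mass_ng(meas.intensity) * _NG_TO_G / meas.n_cells
    accessible_l = fraction * vol.mean_volume * _UM3_TO_L
    conc = mass_per_cell_g / (meas.mw * accessible_l)
    rel2 = 0.0
    if curve.slope_err:
        rel2 += (curve.slope_err / curve.slope) ** 2
    if vol.sd_volume:
        rel2 += (vol.sd_volume / vol.mean_volume) ** 2
    err = conc * np.sqrt(rel2) if rel2 > 0 else None
    return ConcentrationEstimate(conc, err, accessible_volume_fraction=fraction)


def fit_lognormal_volume(samples: Sequence[float], n_expected: int = 300) -> CellVolumeModel:
    """Maximum-likelihood lognormal fit to single-cell volumes (um^3).

    The fit is on the raw samples (bin-free), not on histogram counts;
    reported are the mean and SD of the fitted distribution,
    ``mean = exp(mu + s^2/2)`` and ``sd = mean * sqrt(exp(s^2) - 1)``.
    """
    v = np.asarray(samples, dtype=float)
    if v.size < 30:
        raise InvalidInputError("need >= 30 volume samples")
    if np.any(v <= 0) or not np.all(np.isfinite(v)):
        raise InvalidInputError("volumes must be positive and finite")
    if v.size < n_expected:
        warnings.warn(
            f"only {v.size} volume samples (< {n_expected}); fit may be noisy",
            DataQualityWarning,
        )
    logs = np.log(v)
    mu, s = logs.mean(), logs.std(ddof=0)  # MLE
    mean = float(np.exp(mu + 0.5 * s ** 2))
    sd = float(mean * np.sqrt(np.expm1(s ** 2)))
    return CellVolumeModel(mean_volume=mean, sd_volume=sd, samples=v,
                           meanlog=float(mu), sdlog=float(s))


def soluble_fraction(meas: FractionationMeasurement):
    """Soluble fraction S/(S+P) and absolute soluble concentration.

    Returns ``(fraction, fraction_err, soluble_conc, soluble_conc_err)``
    with first-order propagation of the intensity and total-concentration
    errors (intensity errors default to zero).
    """
    s, p = meas.supernatant_intensity, meas.pellet_intensity
    tot = s + p
    frac = s / tot
    # d(frac)/dS = P/tot^2, d(frac)/dP = -S/tot^2
    frac_err = np.hypot(p * meas.supernatant_err, s * meas.pellet_err) / tot ** 2
    conc = frac * meas.total_concentration
    conc_err = np.hypot(
        frac * meas.total_concentration_err, meas.total_concentration * frac_err
    )
    return float(frac), float(frac_err), float(conc), float(conc_err)


def fit_gaussian_velocity(
    velocities: Sequence[float],
    cell_ids: Optional[Sequence] = None,
    per_cell: bool = False,
    unit: str = "subunits_per_s",
    n_expected: int = 650,
) -> VelocityDistribution:
    """Maximum-likelihood Gaussian fit to single-molecule velocities.

    ``per_cell=True`` first averages molecules within each cell (requires
    ``cell_ids``) and fits the distribution of cell means; the default
    pools all molecules.  Standard errors are the asymptotic MLE values
    ``sigma/sqrt(n)`` and ``sigma/sqrt(2n)``.
    """
    v = np.asarray(velocities, dtype=float)
    if v.size < 2 or np.unique(v).size < 2:
        raise InvalidInputError("need >= 2 distinct velocity values")
    if v.size < 30:
        warnings.warn("fewer than 30 velocities; Gaussian fit may be noisy",
                      DataQualityWarning)
    elif v.size < n_expected:
        warnings.warn(
            f"only {v.size} velocities (< {n_expected}); fit may be noisy",
            DataQualityWarning,
        )
    n_molecules = int(v.size)
    n_cells = None
    sample = v
    if per_cell:
        if cell_ids is None:
            raise InvalidInputError("per_cell fitting requires cell_ids")
        df = pd.DataFrame({"cell": list(cell_ids), "v": v})
        sample = df.groupby("cell")["v"].mean().to_numpy()
        n_cells = int(sample.size)
        if sample.size < 2:
            raise InvalidInputError("per_cell fitting requires >= 2 cells")
    elif cell_ids is not None:
        n_cells = int(pd.unique(pd.Series(list(cell_ids))).size)
    mu = float(sample.mean())
    sigma = float(sample.std(ddof=0))
    if sigma == 0:
        raise InvalidInputError("zero variance: cannot fit a Gaussian")
    n = sample.size
    return VelocityDistribution(
        velocities=v, mu=mu, mu_err=sigma / np.sqrt(n),
        sigma=sigma, sigma_err=sigma / np.sqrt(2 * n),
        n_molecules=n_molecules, n_cells=n_cells, unit=unit,
    )


def velocity_vs_concentration(
    dists: Sequence[VelocityDistribution],
    rel_conc: Sequence[float],
    abs_conc: Optional[Sequence[float]] = None,
):
    """Compare proportional vs. saturating scaling of in vivo velocities.

    Fits the mean velocities against relative profilin-actin levels with a
    line through the origin, and (when absolute concentrations are given
    and at least three conditions exist) with the hyperbolic saturation
    law, reporting the residual sum of squares of each so the buffering
    conclusion can be read off synthetic data.

    Returns ``(table, proportional, hyperbolic)`` where ``proportional``
    is ``{"slope", "rss"}`` and ``hyperbolic`` is a
    :class:`~actinpace.elongation.HyperbolicFit` plus RSS, or ``None``
    with an unidentifiable flag when too few conditions exist.
    """
    rel = np.asarray(rel_conc, dtype=float)
    if len(dists) != rel.size:
        raise InvalidInputError("dists and rel_conc length mismatch")
    mu = np.array([d.mu for d in dists])
    table = pd.DataFrame(
        {
            "rel_conc": rel,
            "mu": mu,
            "mu_err": [d.mu_err for d in dists],
            "sigma": [d.sigma for d in dists],
            "n_molecules": [d.n_molecules for d in dists],
        }
    )
    slope = float((rel * mu).sum() / (rel * rel).sum())
    prop = {"slope": slope, "rss": float(((mu - slope * rel) ** 2).sum())}

    hyper = None
    if abs_conc is not None:
        c = np.asarray(abs_conc, dtype=float)
        if c.size != rel.size:
            raise InvalidInputError("abs_conc length mismatch")
        if c.size >= 3:
            curve = VelocityCurve(
                conc=c, v_mean=mu,
                v_sd=np.array([d.sigma for d in dists]),
                n=np.array([d.n_molecules for d in dists]),
            )
            try:
                fit = fit_hyperbolic(curve)
                rss = float(((mu - fit.velocity(c)) ** 2).sum())
                hyper = {"fit": fit, "rss": rss, "identifiable": True}
            except (FitError, InvalidInputError):
                hyper = {"fit": None, "rss": None, "identifiable": False}
        else:
            hyper = {"fit": None, "rss": None, "identifiable": False}
    return table, prop, hyper
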