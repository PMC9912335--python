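"""Physical interpretation of trapping kinetics.

Converts measured dwell-time constants into fold-changes, trapping-barrier
increases (via the Boltzmann factor tau ~ exp(dG/kBT), assuming the
attempt frequency is unchanged between conditions), mass-scaling fits of
ln tau against molecular mass, and the Stokes viscous drag force on a
trapped protein in the electro-osmotic flow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MassScalingFit",
    "ForceEstimate",
    "fold_change",
    "barrier_increase",
    "stokes_drag",
    "fit_mass_scaling",
]


@dataclass(frozen=True)
class MassScalingFit:
    """Exponential mass scaling tau(M) = tau0 * exp(b M).

    ``ln_tau0`` is the intercept (ln seconds), ``slope`` b in 1/kDa,
    ``residuals`` the per-protein residuals of ln tau.
    """

    ln_tau0: float
    slope: float
    residuals: np.ndarray

    @property
    def tau0(self) -> float:
        return float(np.exp(self.ln_tau0))

    def predict(self, mass_kda) -> np.ndarray:
        return np.exp(self.ln_tau0 + self.slope * np.asarray(mass_kda, float))


@dataclass(frozen=True)
class ForceEstimate:
    """Stokes drag F = 6 pi eta r v on a trapped sphere."""

    viscosity: float
    radius: float
    velocity: float
    force: float


def fold_change(tau_a: float, tau_b: float) -> float:
    """Ratio tau_a / tau_b of two time constants."""
    if tau_b == 0:
        raise ValueError("reference time constant must be nonzero")
    return tau_a / tau_b


def barrier_increase(fold: float) -> float:
    """Trapping-barrier increase in kBT implied by a dwell-time fold-change.

    With tau proportional to exp(dG/kBT) and an unchanged attempt
    frequency, ddG = ln(fold); e.g. a 100-fold longer trapping time
    corresponds to ln(100) = 4.6, i.e. ~5 kBT.
    """
    if fold <= 0:
        raise ValueError("fold-change must be positive")
    return float(np.log(fold))


def stokes_drag(viscosity: float, radius: float, velocity: float) -> ForceEstimate:
    """Viscous drag on a sphere: F = 6 pi eta r v (SI units, F in N)."""
    if viscosity <= 0 or radius <= 0:
        raise ValueError("viscosity and radius must be positive")
    force = 6.0 * np.pi * viscosity * radius * velocity
    return ForceEstimate(viscosity=viscosity, radius=radius, velocity=velocity, force=float(force))


def fit_mass_scaling(points) -> MassScalingFit:
    """Least-squares fit of ln tau = ln tau0 + b*M to (mass_kDa, tau_s) pairs.

    The fit is done in log space (homoscedastic in ln tau, matching an
    exponential mass dependence); at least two distinct masses required.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise ValueError("need at least two (mass, tau) points")
    mass, tau = pts[:, 0], pts[:, 1]
    if np.any(tau <= 0):
        raise ValueError("time constants must be positive")
    if np.unique(mass).size < 2:
        raise ValueError("mass-scaling fit needs at least two distinct masses")
    X = np.column_stack([np.ones_like(mass), mass])
    y = np.log(tau)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return MassScalingFit(ln_tau0=float(coef[0]), slope=float(coef[1]), residuals=resid)
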