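"""Forward models for elastic incoherent neutron scattering (EINS).

Pure, deterministic evaluation of the physics used throughout the
pipeline:

* Arrhenius (Boltzmann) populations of a two-well energy landscape,
* the two-state elastic structure factor on a Gaussian (Debye-Waller)
  baseline,
* the total mean-square displacement (MSD) decomposition into a
  single-well term and an inter-well term,
* the plain Gaussian-approximation intensity, and
* the fractional-Brownian-diffusion (FBD) sub-diffusive MSD law.

Conventions
-----------
The Gaussian intensity is ``I = exp(-q^2 <dx^2>)`` with **no** 1/3
factor and **no** amplitude prefactor.  Neutron-scattering literature
varies on this point; every MSD produced or consumed by this package
uses this convention.  Enthalpies are stored in kJ/mol and converted to
J/mol internally; entropies are stored as the dimensionless ratio
dS/R.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = [
    "GAS_CONSTANT",
    "ThermoParams",
    "WellGeometry",
    "Populations",
    "FBDParams",
    "populations",
    "two_state_intensity",
    "total_msd",
    "gaussian_intensity",
    "fbd_msd",
]

#: Molar gas constant R, J/(mol K).
GAS_CONSTANT = 8.314


@dataclass(frozen=True)
class ThermoParams:
    """Thermodynamics of the two-well landscape.

    Parameters
    ----------
    delta_h : float
        Enthalpy difference between the upper and lower well, kJ/mol.
    delta_s_over_r : float
        Entropy difference divided by the gas constant (dimensionless).
    """

    delta_h: float
    delta_s_over_r: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.delta_h) and np.isfinite(self.delta_s_over_r)):
            raise ValueError("thermodynamic parameters must be finite")

    def free_energy(self, temperature):
        """Free-energy gap dG(T) = dH - T dS in J/mol (linear in T)."""
        t = np.asarray(temperature, dtype=float)
        return self.delta_h * 1e3 - t * self.delta_s_over_r * GAS_CONSTANT


@dataclass(frozen=True)
class WellGeometry:
    """Geometry of the two wells.

    Parameters
    ----------
    d : float
        Distance between the two wells, Angstrom.
    msd0 : float
        Mean-square displacement inside a single well <dx^2>_0, A^2.
    """

    d: float
    msd0: float

    def __post_init__(self) -> None:
        if self.d < 0:
            raise ValueError(f"well separation d must be >= 0, got {self.d}")
        if self.msd0 < 0:
            raise ValueError(f"single-well MSD must be >= 0, got {self.msd0}")


@dataclass(frozen=True)
class Populations:
    """Occupations of the lower (p1) and upper (p2) well; p1 + p2 = 1."""

    p1: float
    p2: float

    def __post_init__(self) -> None:
        s = np.asarray(self.p1) + np.asarray(self.p2)
        if not np.allclose(s, 1.0, atol=1e-9):
            raise ValueError("populations must sum to 1")

    @property
    def product(self):
        """p1*p2, the weight of the inter-well (anharmonic) term."""
        return np.asarray(self.p1) * np.asarray(self.p2)


@dataclass(frozen=True)
class FBDParams:
    """Fractional-Brownian-diffusion parameters MSD(t) = D t^alpha.

    ``D`` is the effective diffusion coefficient (A^2/ps^alpha),
    ``alpha`` the sub-diffusion exponent (alpha = 1 is normal
    diffusion), ``tau`` the instrument resolution time in ps.
    """

    D: float
    alpha: float
    tau: float = 100.0

    def __post_init__(self) -> None:
        if not self.D > 0:
            raise ValueError(f"D must be > 0, got {self.D}")
        if not 0 < self.alpha <= 1:
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")


def populations(temperature, thermo: ThermoParams) -> Populations:
    """Arrhenius populations p2/p1 = exp(-dG/(RT)) of the two wells.

    ``temperature`` may be a scalar or array of temperatures in K;
    fields of the returned :class:`Populations` have the same shape.
    dG may be negative at high T, in which case p2 > p1 (no clamping).
    """
    t = np.asarray(temperature, dtype=float)
    if np.any(t <= 0):
        raise ValueError("temperature must be > 0 K")
    x = thermo.free_energy(t) / (GAS_CONSTANT * t)
    # expit keeps both tails numerically stable (no overflow in exp)
    p2 = expit(-x)
    p1 = expit(x)
    if t.ndim == 0:
        return Populations(float(p1), float(p2))
    return Populations(p1, p2)


def two_state_intensity(q, geom: WellGeometry, pops: Populations):
    """Elastic intensity of the two-state model.

    I(q) = exp(-<dx^2>_0 q^2) * {1 - 2 p1 p2 (1 - sin(qd)/(qd))}

    The sinc factor is defined by its limit 1 at q d = 0.
    """
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise ValueError("momentum transfer q must be >= 0")
    # np.sinc(x) = sin(pi x)/(pi x), exact at 0
    sinc = np.sinc(q * geom.d / np.pi)
    brace = 1.0 - 2.0 * pops.product * (1.0 - sinc)
    return np.exp(-geom.msd0 * q**2) * brace


def total_msd(geom: WellGeometry, pops: Populations):
    """Total MSD: <dx^2>_0 + p1 p2 d^2 / 3.

    Equals the q -> 0 slope of -ln I(q) versus q^2 of
    :func:`two_state_intensity`.
    """
    return geom.msd0 + pops.product * geom.d**2 / 3.0


def gaussian_intensity(q, msd):
    """Gaussian-approximation intensity exp(-q^2 <dx^2>)."""
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise ValueError("momentum transfer q must be >= 0")
    if np.any(np.asarray(msd) < 0):
        raise ValueError("mean-square displacement must be >= 0")
    return np.exp(-(q**2) * msd)


def fbd_msd(t, params: FBDParams):
    """Sub-diffusive MSD law MSD(t) = D t^alpha (t in ps, MSD in A^2)."""
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("time must be > 0")
    return params.D * t**params.alpha
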