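"""Hydrodynamic relations for sedimenting (and floating) particles.

Converts between the molar description of a solute -- molar mass ``M``,
apparent partial specific volume ``vbar`` and frictional ratio ``alpha``
(f/f0) -- and its transport coefficients: sedimentation coefficient ``s``
(Svedberg equation), diffusion coefficient ``D`` (Einstein relation),
frictional coefficient ``f`` and hydrodynamic radius ``Rh`` (Stokes law).

``vbar`` is the *apparent particle* value, i.e. the volume per gram of the
whole sedimenting particle including hydration and bound ions; no anhydrous
correction is applied anywhere in the package.  With that convention the
minimal-sphere radius ``R0`` derived from the particle volume refers to a
sphere of the same (hydrated) volume, so ``alpha >= 1`` with equality for a
sphere and ``Rh = alpha * R0``.

The buoyancy term ``1 - vbar*rho`` controls the sign of sedimentation:
positive means the particle is denser than the solvent and sediments,
negative means it floats, zero is the density-match (isopycnic) point.

All quantities are CGS; ``s`` is in seconds (1 Svedberg = 1e-13 s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import N_AVOGADRO, R_GAS, SVEDBERG

__all__ = [
    "BuoyancyError",
    "BufferState",
    "SoluteHydro",
    "buoyancy",
    "solute_from_mass",
    "solute_from_s_vbar",
    "solute_from_radius",
    "D_from_s_alpha_vbar",
    "mass_from_sD",
    "DEFAULT_BUOYANCY_EXCLUSION",
]

#: Below this |1 - vbar*rho| the parameterized conversions (implied molar
#: masses) diverge; such solutes are excluded from grids and conversions.
DEFAULT_BUOYANCY_EXCLUSION = 1e-4


class BuoyancyError(ValueError):
    """Raised when a conversion is degenerate at or near the density match."""


@dataclass(frozen=True)
class BufferState:
    """Solvent state entering the hydrodynamic relations.

    Parameters
    ----------
    rho : float
        Solvent density, g/mL.
    eta : float
        Solvent viscosity, poise.
    T : float
        Absolute temperature, K.
    """

    rho: float
    eta: float
    T: float

    def __post_init__(self) -> None:
        if not (self.rho > 0 and self.eta > 0 and self.T > 0):
            raise ValueError(
                f"rho, eta, T must be positive, got ({self.rho}, {self.eta}, {self.T})"
            )


@dataclass(frozen=True)
class SoluteHydro:
    """One basis species with all mutually consistent hydrodynamic fields.

    Attributes
    ----------
    M : float
        Molar mass, g/mol.
    vbar : float
        Apparent partial specific volume, mL/g.
    alpha : float
        Frictional ratio f/f0 (>= 1).
    s : float
        Sedimentation coefficient, seconds (negative for floating species).
    D : float
        Diffusion coefficient, cm^2/s.
    f : float
        Frictional coefficient, g/s.
    V : float
        Particle volume, cm^3.
    R0 : float
        Minimal (equal-volume) sphere radius, cm.
    f0 : float
        Frictional coefficient of the minimal sphere, g/s.
    Rh : float
        Hydrodynamic (Stokes) radius, cm; equals alpha * R0.
    """

    M: float
    vbar: float
    alpha: float
    s: float
    D: float
    f: float
    V: float
    R0: float
    f0: float
    Rh: float

    @property
    def s_sv(self) -> float:
        """Sedimentation coefficient in Svedberg."""
        return self.s / SVEDBERG

    @property
    def Rh_nm(self) -> float:
        """Hydrodynamic radius in nm."""
        return self.Rh / 1e-7


def buoyancy(vbar: float, rho: float) -> float:
    """Buoyancy term ``1 - vbar*rho``.

    Positive => sedimentation, negative => flotation, zero => density match.
    """
    if vbar <= 0 or rho <= 0:
        raise ValueError("vbar and rho must be positive")
    return 1.0 - vbar * rho


def solute_from_mass(
    M: float, vbar: float, alpha: float, buffer: BufferState
) -> SoluteHydro:
    """Forward chain: (M, vbar, alpha) -> all transport coefficients.

    V = M*vbar/N; R0 = (3V/4pi)^(1/3); f0 = 6*pi*eta*R0; f = alpha*f0;
    D = RT/(N*f); s = M*(1 - vbar*rho)/(N*f); Rh = f/(6*pi*eta) = alpha*R0.
    """
    if M <= 0:
        raise ValueError(f"M must be positive, got {M}")
    if vbar <= 0:
        raise ValueError(f"vbar must be positive, got {vbar}")
    if alpha < 1.0:
        raise ValueError(f"frictional ratio must be >= 1, got {alpha}")
    V = M * vbar / N_AVOGADRO
    R0 = (3.0 * V / (4.0 * math.pi)) ** (1.0 / 3.0)
    f0 = 6.0 * math.pi * buffer.eta * R0
    f = alpha * f0
    D = R_GAS * buffer.T / (N_AVOGADRO * f)
    s = M * buoyancy(vbar, buffer.rho) / (N_AVOGADRO * f)
    Rh = alpha * R0
    return SoluteHydro(M=M, vbar=vbar, alpha=alpha, s=s, D=D, f=f, V=V,
                       R0=R0, f0=f0, Rh=Rh)


def D_from_s_alpha_vbar(
    s: float,
    alpha: float,
    vbar: float,
    buffer: BufferState,
    exclusion: float = DEFAULT_BUOYANCY_EXCLUSION,
) -> float:
    """Diffusion coefficient parameterized by (s, alpha, vbar).

    D = RT / [ N * 18*pi * (alpha*eta)^(3/2) * sqrt( s*vbar / (2*(1-vbar*rho)) ) ]

    Valid on both sides of the density match as long as sign(s) equals the
    sign of the buoyancy term, so the radicand is positive.
    """
    if alpha < 1.0:
        raise ValueError(f"frictional ratio must be >= 1, got {alpha}")
    b = buoyancy(vbar, buffer.rho)
    if abs(b) < exclusion:
        raise BuoyancyError(
            f"|1 - vbar*rho| = {abs(b):.3g} below exclusion threshold {exclusion:.3g}"
        )
    radicand = s * vbar / (2.0 * b)
    if radicand <= 0:
        raise BuoyancyError(
            f"sign-inconsistent s and buoyancy: s = {s:.3g} s, 1 - vbar*rho = {b:.3g}"
        )
    denom = (
        N_AVOGADRO
        * 18.0
        * math.pi
        * (alpha * buffer.eta) ** 1.5
        * math.sqrt(radicand)
    )
    return R_GAS * buffer.T / denom


def mass_from_sD(
    s: float,
    D: float,
    vbar: float,
    buffer: BufferState,
    exclusion: float = DEFAULT_BUOYANCY_EXCLUSION,
) -> float:
    """Svedberg molar mass: M = s*R*T / (D * (1 - vbar*rho)).

    Inverse of :func:`solute_from_mass`; requires sign(s) == sign(buoyancy).
    """
    if D <= 0:
        raise ValueError(f"D must be positive, got {D}")
    b = buoyancy(vbar, buffer.rho)
    if abs(b) < exclusion:
        raise BuoyancyError(
            f"|1 - vbar*rho| = {abs(b):.3g} below exclusion threshold {exclusion:.3g}"
        )
    if s * b <= 0:
        raise BuoyancyError(
            f"sign-inconsistent s and buoyancy: s = {s:.3g} s, 1 - vbar*rho = {b:.3g}"
        )
    return s * R_GAS * buffer.T / (D * b)


def solute_from_s_vbar(
    s: float,
    vbar: float,
    alpha: float,
    buffer: BufferState,
    exclusion: float = DEFAULT_BUOYANCY_EXCLUSION,
) -> SoluteHydro:
    """Grid parameterization: (s, vbar, alpha) -> full solute.

    Uses the (s, alpha, vbar) parameterization of D and the Svedberg relation
    for M, then rebuilds the remaining fields through the forward chain.
    """
    D = D_from_s_alpha_vbar(s, alpha, vbar, buffer, exclusion=exclusion)
    M = mass_from_sD(s, D, vbar, buffer, exclusion=exclusion)
    sol = solute_from_mass(M, vbar, alpha, buffer)
    return sol


def solute_from_radius(
    Rh: float, vbar: float, alpha: float, buffer: BufferState
) -> SoluteHydro:
    """(Rh, vbar, alpha) -> full solute; used by the synthetic-data sampler.

    Inverts Rh = alpha * R0 and V = (4/3)*pi*R0^3 = M*vbar/N for M.
    """
    if Rh <= 0:
        raise ValueError(f"Rh must be positive, got {Rh}")
    R0 = Rh / alpha
    V = 4.0 / 3.0 * math.pi * R0**3
    M = V * N_AVOGADRO / vbar
    return solute_from_mass(M, vbar, alpha, buffer)


def s20w_like_correction(s: np.ndarray, eta: float, eta_ref: float) -> np.ndarray:
    """Viscosity-only rescaling of sedimentation coefficients.

    Multiplies every s by eta/eta_ref, preserving signs.  Deliberately does
    not correct for solvent density: in density matching the density
    dependence is the signal being extrapolated.
    """
    return np.asarray(s, dtype=float) * (eta / eta_ref)
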