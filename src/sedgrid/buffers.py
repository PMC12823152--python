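"""Density and viscosity of H2O/D2O (PBS) mixtures at run temperature.

Reference tables for pure H2O and pure D2O at 1 atm are bundled below
(0-40 degC in 5 degC steps) and interpolated in temperature; the mixture is
interpolated linearly in D2O volume fraction -- density directly, viscosity
through the D2O/H2O viscosity ratio applied to the H2O value.  Salts (PBS)
enter as a constant density increment and a viscosity multiplier.  For work
requiring better than table accuracy, explicit (rho, eta) overrides bypass
the tables entirely.

H2O densities follow Kell's compilation; H2O viscosities the IAPWS-consistent
handbook values; D2O values are standard handbook data (density maximum near
11 degC; viscosity about 25% above H2O at room temperature).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hydro import BufferState

__all__ = ["BufferSpec", "buffer_state", "PBS_DENSITY_INCREMENT"]

#: Density added by 1x PBS salts, g/mL (applies at every D2O fraction: the
#: salt mix is reconstituted in D2O before mixing).
PBS_DENSITY_INCREMENT = 0.0046

_T_C = np.array([0.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0, 35.0, 40.0])

# pure H2O density, g/mL
_RHO_H2O = np.array([
    0.9998425, 0.9999668, 0.9997026, 0.9991026, 0.9982071,
    0.9970479, 0.9956502, 0.9940349, 0.9922187,
])

# pure D2O density, g/mL
_RHO_D2O = np.array([
    1.10469, 1.10553, 1.10586, 1.10577, 1.10534,
    1.10445, 1.10323, 1.10173, 1.09996,
])

# pure H2O viscosity, poise
_ETA_H2O = np.array([
    0.017914, 0.015188, 0.013060, 0.011375, 0.010016,
    0.008900, 0.007972, 0.007190, 0.006527,
])

# D2O/H2O viscosity ratio
_ETA_RATIO = np.array([
    1.278, 1.266, 1.255, 1.250, 1.2447,
    1.2303, 1.222, 1.213, 1.205,
])


@dataclass(frozen=True)
class BufferSpec:
    """Composition of one run buffer.

    Parameters
    ----------
    d2o_fraction : float
        D2O volume fraction, 0-1.
    base_density_increment : float
        Density added by dissolved salts, g/mL (default 1x PBS).
    viscosity_multiplier : float
        Relative viscosity of the salt solution vs pure solvent (default 1).
    T : float
        Absolute temperature, K.
    rho_override, eta_override : float, optional
        Explicit values that bypass the tables when given.
    """

    d2o_fraction: float = 0.0
    base_density_increment: float = PBS_DENSITY_INCREMENT
    viscosity_multiplier: float = 1.0
    T: float = 293.15
    rho_override: float | None = None
    eta_override: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.d2o_fraction <= 1.0:
            raise ValueError(
                f"d2o_fraction must be in [0, 1], got {self.d2o_fraction}"
            )

    def state(self) -> BufferState:
        return buffer_state(self)


def _interp_T(table: np.ndarray, T: float) -> float:
    t_c = T - 273.15
    if not (_T_C[0] <= t_c <= _T_C[-1]):
        raise ValueError(
            f"temperature {t_c:.2f} degC outside tabulated range "
            f"[{_T_C[0]:.0f}, {_T_C[-1]:.0f}] degC"
        )
    return float(np.interp(t_c, _T_C, table))


def buffer_state(spec: BufferSpec) -> BufferState:
    """Realize a :class:`BufferSpec` into (rho, eta, T).

    Linear volume-fraction mixing between the H2O and D2O reference values at
    the run temperature, plus the salt increment/multiplier; explicit
    overrides win over the tables.
    """
    phi = spec.d2o_fraction
    if spec.rho_override is not None:
        rho = spec.rho_override
    else:
        rho_h = _interp_T(_RHO_H2O, spec.T)
        rho_d = _interp_T(_RHO_D2O, spec.T)
        rho = (1.0 - phi) * rho_h + phi * rho_d + spec.base_density_increment
    if spec.eta_override is not None:
        eta = spec.eta_override
    else:
        eta_h = _interp_T(_ETA_H2O, spec.T)
        ratio = _interp_T(_ETA_RATIO, spec.T)
        eta = eta_h * (1.0 + phi * (ratio - 1.0)) * spec.viscosity_multiplier
    return BufferState(rho=rho, eta=eta, T=spec.T)
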