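"""Physical constants and thermal-exchange parameters.

The defaults are the constants used when the shipped coefficient presets
were fitted; overriding them invalidates the presets' calibration, so
they are exposed as an immutable :class:`ThermalConstants` object that
must be replaced wholesale rather than mutated.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DomainError

#: K at 0 degC (exact offset of the Celsius scale)
CELSIUS_ZERO = 273.15

#: Stefan-Boltzmann constant, W m-2 K-4, at the precision used for the presets
STEFAN_BOLTZMANN = 5.669e-8

#: Wien displacement constant, um K
WIEN_B = 2897.77

#: Global-radiation threshold separating shade from sunshine, W m-2.
#: Visits with G strictly above this value count as "sun".
SUN_THRESHOLD = 100.0


def to_kelvin(t_celsius, allow_absolute_zero: bool = True):
    """Convert Celsius to Kelvin, rejecting unphysical temperatures.

    Array-aware. With ``allow_absolute_zero`` the boundary value
    -273.15 degC maps to 0 K (radiative fluxes vanish there); otherwise it
    is rejected too (e.g. Wien's law diverges).
    """
    t = np.asarray(t_celsius, dtype=float)
    kelvin = t + CELSIUS_ZERO
    bad = (kelvin < 0.0) | ((kelvin == 0.0) & (not allow_absolute_zero))
    if np.any(bad):
        raise DomainError(
            f"temperature {'below' if allow_absolute_zero else 'at or below'} "
            f"absolute zero: {t[bad] if t.ndim else float(t)} degC"
        )
    return kelvin if kelvin.ndim else float(kelvin)


@dataclass(frozen=True)
class ThermalConstants:
    """Fixed physical parameters of the heat-exchange model.

    Parameters
    ----------
    epsilon_b
        Infrared emissivity of the bee cuticle (dimensionless).
    alpha_b_ir
        Infrared absorptivity of the body; equals ``epsilon_b`` by
        Kirchhoff's law for the cuticle.
    alpha_b_sol
        Solar (visible + near-IR) absorptivity, already corrected for
        reduced absorption towards the curved body edges.
    alpha_paint
        Absorptivity of the black paint of the measurement chamber;
        only used by the optional reflected-solar term.
    sigma
        Stefan-Boltzmann constant, W m-2 K-4.
    E_ev
        Evaporative heat loss, W. Held constant across ambient
        temperature because foragers' mouthparts are wet from drinking
        under all conditions.
    """

    epsilon_b: float = 0.97
    alpha_b_ir: float = 0.97
    alpha_b_sol: float = 0.825
    alpha_paint: float = 0.95
    sigma: float = STEFAN_BOLTZMANN
    E_ev: float = 0.004

    def __post_init__(self) -> None:
        for name in ("epsilon_b", "alpha_b_ir", "alpha_b_sol", "alpha_paint"):
            value = getattr(self, name)
            if not 0.0 < value <= 1.0:
                raise DomainError(f"{name} must be in (0, 1], got {value}")
        if self.sigma <= 0:
            raise DomainError(f"sigma must be positive, got {self.sigma}")
        if self.E_ev < 0:
            raise DomainError(f"E_ev must be non-negative, got {self.E_ev}")


#: Default constants; the values the shipped presets were fitted with.
DEFAULT_CONSTANTS = ThermalConstants()
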