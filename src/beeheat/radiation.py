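"""Radiative heat exchange of the bee body.

Loss is grey-body emission over the full body surface
(Stefan-Boltzmann). Gain splits into a long-wave infrared part and a
short-wave solar part; each incident flux is assumed to act on half the
body surface only (the upper half for sky/solar components, the lower
half for ground-emitted IR).

The IR gain uses a surround-as-blackbody closure: direct and
ground-emitted components are both blackbody fluxes at an explicit
surround temperature (default: ambient air), and reflected IR is zero
because the measurement-chamber paint is nearly black in the IR. Other
closures can be expressed by passing a different surround temperature.
All interfaces are in degC; Kelvin conversion is internal.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import DEFAULT_CONSTANTS, WIEN_B, ThermalConstants, to_kelvin
from .exceptions import DomainError


def _check_area(A_b) -> None:
    if np.any(np.asarray(A_b) <= 0):
        raise DomainError(f"body area must be positive, got {A_b}")


def radiative_loss(T_b, A_b, constants: ThermalConstants = DEFAULT_CONSTANTS):
    """IR emission eps_b * sigma * T_b^4 * A_b (T_b in degC, A_b in m^2) -> W."""
    _check_area(A_b)
    T = to_kelvin(T_b)
    return constants.epsilon_b * constants.sigma * np.asarray(T) ** 4 * A_b


def ir_gain(T_surround, A_b, constants: ThermalConstants = DEFAULT_CONSTANTS):
    """Absorbed long-wave IR for a blackbody surround at ``T_surround`` degC -> W.

    Direct (sky) and ground-emitted components each act on A_b/2 and
    carry the same blackbody flux sigma*T^4; reflected IR is zero, so the
    total is alpha_b_ir * sigma * T^4 * A_b.
    """
    _check_area(A_b)
    T = to_kelvin(T_surround)
    return constants.alpha_b_ir * constants.sigma * np.asarray(T) ** 4 * A_b


def solar_gain(
    G,
    A_b,
    constants: ThermalConstants = DEFAULT_CONSTANTS,
    include_reflected: bool = False,
):
    """Absorbed short-wave radiation for global radiation ``G`` (W m-2) -> W.

    Direct term alpha_b_sol * G * A_b/2. The reflected term is zero by
    default (global radiation was measured directly; the chamber floor
    is nearly black); ``include_reflected`` adds
    alpha_b_sol * (1 - alpha_paint) * G * A_b/2 for sensitivity analysis.
    """
    _check_area(A_b)
    G = np.asarray(G, dtype=float)
    if np.any(G < 0):
        raise DomainError("global radiation must be non-negative")
    half = np.asarray(A_b, dtype=float) / 2.0
    gain = constants.alpha_b_sol * G * half
    if include_reflected:
        gain = gain + constants.alpha_b_sol * (1.0 - constants.alpha_paint) * G * half
    return gain


@dataclass(frozen=True)
class RadiationBudget:
    """Radiative components of a visit (all W): loss, IR gain, solar gain
    and their sum R_gain = R_gIR + R_gSOL."""

    R_loss: object
    R_gIR: object
    R_gSOL: object
    R_gain: object


def radiation_budget(
    T_b,
    G,
    A_b,
    constants: ThermalConstants = DEFAULT_CONSTANTS,
    T_surround=None,
    include_reflected: bool = False,
) -> RadiationBudget:
    """Full radiative budget; ``T_surround`` defaults to ``T_b``'s ambient
    counterpart must be supplied by the caller (predict passes T_a)."""
    if T_surround is None:
        raise ValueError("T_surround is required (pass ambient air temperature)")
    loss = radiative_loss(T_b, A_b, constants)
    gir = ir_gain(T_surround, A_b, constants)
    gsol = solar_gain(G, A_b, constants, include_reflected)
    return RadiationBudget(R_loss=loss, R_gIR=gir, R_gSOL=gsol, R_gain=gir + gsol)


def wien_peak_wavelength(T):
    """Peak emission wavelength b/T (T in degC) -> um; diverges at 0 K."""
    T_K = to_kelvin(T, allow_absolute_zero=False)
    return WIEN_B / np.asarray(T_K)
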