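"""Model variants: convection terms and forward prediction of energy turnover.

Energy turnover of a stationary forager in thermal steady state is
modelled as

    M = r_l * R_loss - r_g * R_gain + E_cv + e_lev * E_ev   [W]

with the radiative terms from :mod:`beeheat.radiation`, a constant
evaporative loss E_ev, conduction neglected, and the convective term
E_cv parameterized per variant:

``simple``
    one body-wide coefficient, E_cv = h_b * A_b * (T_b - T_a), with T_b
    the unweighted mean of the head, thorax and abdomen surface
    temperatures;
``per_part`` / ``per_part_reduced``
    one coefficient per body part, each a linear function of ambient
    temperature, h_xx = a_hxx + b_hxx * T_a (the reduced form holds the
    abdomen coefficient constant);
``three_compartment`` / ``three_compartment_reduced``
    head and abdomen terms driven by the thorax-to-part temperature
    differences (heat carried by haemolymph circulation and respiration)
    instead of part-to-air excess; only the thorax term carries an area
    factor, so the head/abdomen coefficients are absolute (W/degC).

The model is linear in every coefficient; the fitted coefficients fold
in physiological regulation, so negative values are legitimate (a body
part receiving more heat than it loses).

Visit data are handled as pandas DataFrames with the canonical columns
``T_a_C, T_hd_C, T_th_C, T_ab_C, G_Wm2`` (plus optional ``M_mW``,
``condition``); single visits can be wrapped in :class:`VisitRecord`.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .constants import DEFAULT_CONSTANTS, SUN_THRESHOLD, ThermalConstants, to_kelvin
from .exceptions import DomainError, VariantMismatchError
from .geometry import DEFAULT_SURFACE, BodySurface
from .radiation import radiation_budget

W_TO_MW = 1000.0

#: Coefficient schema per variant, in canonical (fitting) order.
VARIANT_COEFFICIENTS: dict[str, tuple[str, ...]] = {
    "simple": ("r_l", "r_g", "e_lev", "h_b"),
    "per_part": (
        "r_l", "r_g", "e_lev",
        "a_hhd", "b_hhd", "a_hth", "b_hth", "a_hab", "b_hab",
    ),
    "per_part_reduced": (
        "r_l", "r_g", "e_lev",
        "a_hhd", "b_hhd", "a_hth", "b_hth", "h_ab",
    ),
    "three_compartment": (
        "r_l", "r_g", "e_lev",
        "a_hthhd", "b_hthhd", "a_hth", "b_hth", "a_hthab", "b_hthab",
    ),
    "three_compartment_reduced": (
        "r_l", "r_g", "e_lev",
        "a_hthhd", "b_hthhd", "a_hth", "b_hth", "h_thab",
    ),
}

VARIANTS = tuple(VARIANT_COEFFICIENTS)

_TEMP_COLUMNS = ("T_a_C", "T_hd_C", "T_th_C", "T_ab_C")
_REQUIRED_COLUMNS = _TEMP_COLUMNS + ("G_Wm2",)


@dataclass(frozen=True)
class VisitRecord:
    """One stay of a forager at a flower."""

    T_hd: float
    T_th: float
    T_ab: float
    T_a: float
    G: float
    M_measured: float | None = None  # mW
    condition: str | None = None

    def __post_init__(self) -> None:
        to_kelvin([self.T_hd, self.T_th, self.T_ab, self.T_a])
        if self.G < 0:
            raise DomainError(f"global radiation must be non-negative, got {self.G}")

    @property
    def is_sun(self) -> bool:
        """Sunshine classification: G strictly above the 100 W m-2 threshold."""
        return self.G > SUN_THRESHOLD

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "T_a_C": [self.T_a],
                "T_hd_C": [self.T_hd],
                "T_th_C": [self.T_th],
                "T_ab_C": [self.T_ab],
                "G_Wm2": [self.G],
                "M_mW": [np.nan if self.M_measured is None else self.M_measured],
                "condition": [self.condition],
            }
        )


def as_visit_frame(data) -> pd.DataFrame:
    """Coerce a VisitRecord, mapping of columns, or DataFrame to the
    canonical visit DataFrame."""
    if isinstance(data, VisitRecord):
        return data.to_frame()
    if isinstance(data, pd.DataFrame):
        frame = data
    elif isinstance(data, Mapping):
        frame = pd.DataFrame({k: np.atleast_1d(v) for k, v in data.items()})
    else:
        raise TypeError(f"cannot interpret {type(data).__name__} as visit data")
    missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise VariantMismatchError(f"visit data missing columns: {missing}")
    return frame


@dataclass(frozen=True)
class CoefficientSet:
    """A model variant plus its full coefficient vector.

    Coefficients are stored by name and validated against the variant's
    schema; the fitted values are meaningful only as a complete set
    (they are not determined independently of each other).
    """

    variant: str
    values: Mapping[str, float]
    name: str | None = None
    note: str | None = None

    def __post_init__(self) -> None:
        if self.variant not in VARIANT_COEFFICIENTS:
            raise VariantMismatchError(
                f"unknown variant {self.variant!r}; expected one of {VARIANTS}"
            )
        schema = VARIANT_COEFFICIENTS[self.variant]
        got = tuple(self.values)
        if set(got) != set(schema):
            raise VariantMismatchError(
                f"variant {self.variant!r} requires coefficients {schema}, got {got}"
            )
        object.__setattr__(self, "values", dict(self.values))

    def __getitem__(self, key: str) -> float:
        return self.values[key]

    @property
    def names(self) -> tuple[str, ...]:
        return VARIANT_COEFFICIENTS[self.variant]

    def as_array(self) -> np.ndarray:
        """Coefficient vector in canonical schema order."""
        return np.array([self.values[k] for k in self.names], dtype=float)

    @classmethod
    def from_array(
        cls, variant: str, vector, name: str | None = None, note: str | None = None
    ) -> "CoefficientSet":
        schema = VARIANT_COEFFICIENTS[variant]
        vector = np.asarray(vector, dtype=float)
        if vector.shape != (len(schema),):
            raise VariantMismatchError(
                f"variant {variant!r} needs {len(schema)} coefficients, got {vector.shape}"
            )
        return cls(variant, dict(zip(schema, vector)), name=name, note=note)


def body_mean_temperature(data):
    """T_b: unweighted mean of head, thorax and abdomen surface temperature."""
    frame = as_visit_frame(data)
    return (
        frame["T_hd_C"].to_numpy(float)
        + frame["T_th_C"].to_numpy(float)
        + frame["T_ab_C"].to_numpy(float)
    ) / 3.0


def convection_basis(data, variant: str, surface: BodySurface = DEFAULT_SURFACE) -> np.ndarray:
    """Regressor columns of the variant's convective term, one per free
    convection coefficient, in schema order. E_cv = basis @ coefficients."""
    frame = as_visit_frame(data)
    T_a = frame["T_a_C"].to_numpy(float)
    T_hd = frame["T_hd_C"].to_numpy(float)
    T_th = frame["T_th_C"].to_numpy(float)
    T_ab = frame["T_ab_C"].to_numpy(float)

    if variant == "simple":
        T_b = body_mean_temperature(frame)
        return np.column_stack([surface.A_b * (T_b - T_a)])

    d_hd = T_hd - T_a
    d_th = T_th - T_a
    d_ab = T_ab - T_a
    if variant in ("per_part", "per_part_reduced"):
        hd = surface.A_hd * d_hd
        th = surface.A_th * d_th
        ab = surface.A_ab * d_ab
        cols = [hd, T_a * hd, th, T_a * th, ab]
        if variant == "per_part":
            cols.append(T_a * ab)
        return np.column_stack(cols)
    if variant in ("three_compartment", "three_compartment_reduced"):
        thhd = T_th - T_hd
        th = surface.A_th * d_th
        thab = T_th - T_ab
        cols = [thhd, T_a * thhd, th, T_a * th, thab]
        if variant == "three_compartment":
            cols.append(T_a * thab)
        return np.column_stack(cols)
    raise VariantMismatchError(f"unknown variant {variant!r}")


def _convection(data, coeffs: CoefficientSet, surface: BodySurface) -> np.ndarray:
    basis = convection_basis(data, coeffs.variant, surface)
    conv_coeffs = coeffs.as_array()[3:]
    return basis @ conv_coeffs


def convection_simple(data, h_b: float, surface: BodySurface = DEFAULT_SURFACE) -> np.ndarray:
    """E_cv = h_b * A_b * (T_b - T_a), W."""
    frame = as_visit_frame(data)
    return h_b * surface.A_b * (body_mean_temperature(frame) - frame["T_a_C"].to_numpy(float))


def convection_per_part(
    data, coeffs: CoefficientSet, surface: BodySurface = DEFAULT_SURFACE
) -> np.ndarray:
    """Per-part convection, W: each part's h is a_hxx + b_hxx * T_a
    (abdomen constant in the reduced variant)."""
    if coeffs.variant not in ("per_part", "per_part_reduced"):
        raise VariantMismatchError(
            f"convection_per_part requires a per_part variant, got {coeffs.variant!r}"
        )
    return _convection(data, coeffs, surface)


def convection_three_compartment(
    data, coeffs: CoefficientSet, surface: BodySurface = DEFAULT_SURFACE
) -> np.ndarray:
    """Three-compartment convection, W: head and abdomen terms driven by
    thorax-to-part temperature differences (no area factor)."""
    if coeffs.variant not in ("three_compartment", "three_compartment_reduced"):
        raise VariantMismatchError(
            "convection_three_compartment requires a three_compartment variant, "
            f"got {coeffs.variant!r}"
        )
    return _convection(data, coeffs, surface)


@dataclass(frozen=True)
class ModelPrediction:
    """Predicted energy turnover and its additive components (all W).

    M = radiative_loss_term - radiative_gain_term + convection
        + evaporation_term, exactly.
    """

    M: np.ndarray
    radiative_loss_term: np.ndarray
    radiative_gain_term: np.ndarray
    convection: np.ndarray
    evaporation_term: np.ndarray

    @property
    def M_mW(self) -> np.ndarray:
        return self.M * W_TO_MW


def predict_metabolism(
    data,
    coeffs: CoefficientSet,
    surface: BodySurface = DEFAULT_SURFACE,
    constants: ThermalConstants = DEFAULT_CONSTANTS,
    T_surround=None,
    include_reflected: bool = False,
) -> ModelPrediction:
    """Forward-predict metabolic energy turnover for each visit.

    ``T_surround`` sets the IR-gain closure temperature; by default the
    surroundings are taken at ambient air temperature.
    """
    frame = as_visit_frame(data)
    T_b = body_mean_temperature(frame)
    if T_surround is None:
        T_surround = frame["T_a_C"].to_numpy(float)
    budget = radiation_budget(
        T_b,
        frame["G_Wm2"].to_numpy(float),
        surface.A_b,
        constants,
        T_surround=T_surround,
        include_reflected=include_reflected,
    )
    loss_term = coeffs["r_l"] * np.asarray(budget.R_loss)
    gain_term = coeffs["r_g"] * np.asarray(budget.R_gain)
    e_cv = _convection(frame, coeffs, surface)
    ev_term = coeffs["e_lev"] * constants.E_ev * np.ones_like(e_cv)
    return ModelPrediction(
        M=loss_term - gain_term + e_cv + ev_term,
        radiative_loss_term=loss_term,
        radiative_gain_term=gain_term,
        convection=e_cv,
        evaporation_term=ev_term,
    )


def conductance_estimate(M_mW, T_b, T_a):
    """Heat-conductance estimate M / (T_b - T_a) in mW/degC.

    Undefined where T_b == T_a; reported as NaN, not raised.
    """
    M_mW = np.asarray(M_mW, dtype=float)
    dT = np.asarray(T_b, dtype=float) - np.asarray(T_a, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(dT == 0.0, np.nan, M_mW / np.where(dT == 0.0, np.nan, dT))
    return out if out.ndim else float(out)
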