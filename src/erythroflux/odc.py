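"""Hemoglobin oxygen-dissociation curve (ODC) and p50 under allosteric effectors.

Implements the revised closed-form Dash–Bassingthwaighte parameterization of the
dependence of p50 — the O2 partial pressure at 50% hemoglobin saturation — on
plasma pH, pCO2, erythrocyte 2,3-BPG and temperature. Each effector contributes a
cubic/quadratic correction polynomial in its deviation from the standard state
(pH 7.40, pCO2 40 mmHg, 2,3-BPG 4.65 mM, 37 °C, where p50 = 26.8 mmHg); the four
corrections compose multiplicatively. Saturation is then a Hill curve with a
pO2-dependent Hill exponent, parameterized directly by p50 so that
``saturation(p50) == 0.5`` holds by construction.

Plasma pH is converted to erythrocyte pH with the standard linear Donnan
relation ``pH_rbc = 0.795 pH_pl + 1.357`` before the pH correction is applied.

2,3-BPG is accepted in mM; converting from assay units (e.g. mmol per g Hb) is
the caller's responsibility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError, PhysiologicalRangeWarning

__all__ = [
    "BloodGasState",
    "OdcCurve",
    "P50Shift",
    "STANDARD_STATE",
    "P50_STANDARD_MMHG",
    "p50_adjusted",
    "saturation",
    "build_curve",
    "delta_p50",
]

#: Standard p50 (mmHg) at the reference effector state.
P50_STANDARD_MMHG = 26.8

# Reference effector values (plasma pH; pCO2 mmHg; 2,3-BPG mM; temperature °C).
PH_PLASMA_STD = 7.40
PCO2_STD_MMHG = 40.0
DPG_STD_MM = 4.65
TEMP_STD_C = 37.0

# Plasma-to-erythrocyte pH conversion (linear Donnan relation).
PH_RBC_SLOPE = 0.795
PH_RBC_INTERCEPT = 1.357

# Correction polynomial coefficients (revised parameterization), applied to the
# deviation of each effector from its reference value. DPG deviation is in molar.
PH_COEFFS = (-25.535, 10.646, -1.764)
PCO2_COEFFS = (1.273e-1, 1.083e-4)
DPG_COEFFS = (7.95633e2, -1.96617e4)
TEMP_COEFFS = (1.435, 4.163e-2, 6.86e-4)

# Hill exponent n(pO2) = HILL_ALPHA - HILL_BETA * 10^(-pO2 / HILL_GAMMA).
HILL_ALPHA = 2.82
HILL_BETA = 1.20
HILL_GAMMA_MMHG = 29.25

# Published validity envelope; states outside it warn but still evaluate.
VALID_RANGES = {
    "ph": (6.8, 7.8),
    "pco2": (10.0, 90.0),
    "dpg": (1.0, 10.0),
    "temp": (34.0, 42.0),
}


@dataclass(frozen=True)
class BloodGasState:
    """One participant-condition-timepoint effector panel.

    Attributes
    ----------
    po2, pco2 : mmHg
    ph : plasma pH
    dpg : erythrocyte 2,3-BPG, mM
    temp : °C
    hct : hematocrit fraction
    hb : hemoglobin, g/dL
    """

    po2: float = 100.0
    pco2: float = PCO2_STD_MMHG
    ph: float = PH_PLASMA_STD
    dpg: float = DPG_STD_MM
    temp: float = TEMP_STD_C
    hct: float = 0.45
    hb: float = 15.0

    def __post_init__(self) -> None:
        if self.po2 < 0 or self.pco2 < 0:
            raise InvalidParameterError("po2 and pco2 must be >= 0 mmHg")
        if not 6.5 < self.ph < 8.0:
            raise InvalidParameterError(f"ph={self.ph} outside (6.5, 8.0)")
        if self.dpg < 0:
            raise InvalidParameterError("dpg must be >= 0 mM")
        if not 30.0 < self.temp < 44.0:
            raise InvalidParameterError(f"temp={self.temp} outside (30, 44) °C")
        if not 0.0 < self.hct < 1.0:
            raise InvalidParameterError("hct must lie in (0, 1)")

    def range_violations(self) -> tuple[str, ...]:
        out = []
        for name, (lo, hi) in VALID_RANGES.items():
            v = getattr(self, name)
            if not lo <= v <= hi:
                out.append(f"{name}={v} outside validity range [{lo}, {hi}]")
        return tuple(out)


def _poly(coeffs: tuple[float, ...], x: float) -> float:
    return sum(c * x ** (i + 1) for i, c in enumerate(coeffs))


def p50_adjusted(state: BloodGasState) -> float:
    """p50 (mmHg) for an effector state; equals 26.8 at the standard state.

    Out-of-range states emit a :class:`PhysiologicalRangeWarning` and are still
    evaluated, because post-exercise panels sit near the validity edge.
    """
    violations = state.range_violations()
    if violations:
        warnings.warn(
            "; ".join(violations), PhysiologicalRangeWarning, stacklevel=2
        )
    ph_rbc = PH_RBC_SLOPE * state.ph + PH_RBC_INTERCEPT
    ph_rbc_std = PH_RBC_SLOPE * PH_PLASMA_STD + PH_RBC_INTERCEPT
    p50_ph = P50_STANDARD_MMHG + _poly(PH_COEFFS, ph_rbc - ph_rbc_std)
    p50_co2 = P50_STANDARD_MMHG + _poly(PCO2_COEFFS, state.pco2 - PCO2_STD_MMHG)
    p50_dpg = P50_STANDARD_MMHG + _poly(DPG_COEFFS, (state.dpg - DPG_STD_MM) * 1e-3)
    p50_t = P50_STANDARD_MMHG + _poly(TEMP_COEFFS, state.temp - TEMP_STD_C)
    return (
        P50_STANDARD_MMHG
        * (p50_ph / P50_STANDARD_MMHG)
        * (p50_co2 / P50_STANDARD_MMHG)
        * (p50_dpg / P50_STANDARD_MMHG)
        * (p50_t / P50_STANDARD_MMHG)
    )


def _hill_exponent(po2):
    return HILL_ALPHA - HILL_BETA * 10.0 ** (-np.asarray(po2, dtype=float) / HILL_GAMMA_MMHG)


def saturation(po2, state: BloodGasState):
    """Fractional HbO2 saturation at ``po2`` (mmHg); scalar or array.

    Hill curve anchored at ``p50_adjusted(state)``: saturation(0) = 0,
    saturation(p50) = 0.5, limit 1 as pO2 → ∞.
    """
    po2_arr = np.asarray(po2, dtype=float)
    if np.any(po2_arr < 0):
        raise InvalidParameterError("po2 must be >= 0 mmHg")
    p50 = p50_adjusted(state)
    n = _hill_exponent(po2_arr)
    with np.errstate(divide="ignore"):
        ratio_n = np.where(po2_arr > 0, (po2_arr / p50) ** n, 0.0)
    sat = ratio_n / (1.0 + ratio_n)
    return float(sat) if np.isscalar(po2) else sat


@dataclass(frozen=True)
class OdcCurve:
    po2_grid: np.ndarray
    saturation: np.ndarray
    p50: float
    state: BloodGasState = field(repr=False)

    def to_records(self) -> list[dict[str, float]]:
        return [
            {"po2_mmHg": float(p), "saturation": float(s)}
            for p, s in zip(self.po2_grid, self.saturation)
        ]


def build_curve(state: BloodGasState, po2_grid=None) -> OdcCurve:
    """Evaluate the ODC on a pO2 grid (default 0–150 mmHg, 1 mmHg steps)."""
    if po2_grid is None:
        po2_grid = np.arange(0.0, 150.5, 1.0)
    po2_grid = np.asarray(po2_grid, dtype=float)
    if po2_grid.size == 0:
        raise InvalidParameterError("po2_grid must be non-empty")
    if np.any(np.diff(po2_grid) <= 0):
        raise InvalidParameterError("po2_grid must be strictly increasing")
    return OdcCurve(
        po2_grid=po2_grid,
        saturation=saturation(po2_grid, state),
        p50=p50_adjusted(state),
        state=state,
    )


@dataclass(frozen=True)
class P50Shift:
    delta_mmHg: float
    label: str


def delta_p50(state_a: BloodGasState, state_b: BloodGasState) -> P50Shift:
    """p50(state_b) − p50(state_a), labelled as a right/left shift of the ODC."""
    delta = p50_adjusted(state_b) - p50_adjusted(state_a)
    if delta > 0:
        label = "right shift"
    elif delta < 0:
        label = "left shift"
    else:
        label = "no shift"
    return P50Shift(delta_mmHg=delta, label=label)
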