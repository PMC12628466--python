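"""Oxygen-carrying-capacity audits: hemolysis and methemoglobin arithmetic.

Hemolysis releases hemoglobin into plasma, where it no longer carries oxygen
inside cells; methemoglobin (Fe3+) cannot bind oxygen at all. Both audits are
unit-agnostic as long as every field of a panel shares the same unit (g/L or
g/dL); the panel records which.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InvalidParameterError, UndefinedRatioError

__all__ = ["HbPanel", "functional_hb", "methb_percent"]


@dataclass(frozen=True)
class HbPanel:
    """Total, plasma (cell-free) and methemoglobin, in one shared unit."""

    total_hb: float
    plasma_hb: float = 0.0
    methb: float = 0.0
    unit: str = "g/L"

    def __post_init__(self) -> None:
        if self.total_hb < 0:
            raise InvalidParameterError("total_hb must be >= 0")
        if not 0 <= self.plasma_hb <= self.total_hb:
            raise InvalidParameterError("plasma_hb must lie in [0, total_hb]")
        if not 0 <= self.methb <= self.total_hb:
            raise InvalidParameterError("methb must lie in [0, total_hb]")


def functional_hb(panel: HbPanel) -> float:
    """Cell-bound (functional) hemoglobin: total minus plasma-free."""
    return panel.total_hb - panel.plasma_hb


def methb_percent(panel: HbPanel) -> float:
    """Methemoglobin as a percentage of total hemoglobin."""
    if panel.total_hb <= 0:
        raise UndefinedRatioError("total_hb must be > 0 to form a percentage")
    return 100.0 * panel.methb / panel.total_hb
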