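"""Radiation response of non-growing follicles.

NGFs are among the most radiosensitive cells in the body, with a median
lethal dose (LD50) conservatively estimated at 2 Gy.  Killing is modelled
as single-hit exponential: the surviving fraction after total physical dose
``d`` is ``S(d) = 2^(-d / LD50)``, the unique memoryless law with the given
LD50 — survival is multiplicative over split doses and fractionation
schedule is deliberately ignored (doses are totals to the ovary).

Proton doses expressed in Cobalt Gray Equivalent (CGE, physical dose with a
constant relative biological effectiveness of 1.1 already applied) are
treated as numerically equal to photon Gy; only the unit label differs.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

from .errors import DoseValidationError

__all__ = ["Modality", "RadiationResponse", "DEFAULT_LD50_GY"]

DEFAULT_LD50_GY = 2.0


class Modality(str, enum.Enum):
    PHOTON = "photon"
    PROTON = "proton"

    @classmethod
    def coerce(cls, value) -> "Modality":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).lower())
        except ValueError:
            raise DoseValidationError(
                f"unknown modality {value!r}; expected one of "
                f"{[m.value for m in cls]}"
            ) from None

    @property
    def dose_unit(self) -> str:
        """Reporting unit: Gy for photons, CGE for protons."""
        return "CGE" if self is Modality.PROTON else "Gy"


@dataclass(frozen=True)
class RadiationResponse:
    """Dose-to-survival mapping for the follicle population."""

    ld50_gy: float = DEFAULT_LD50_GY

    def __post_init__(self):
        if not (self.ld50_gy > 0):
            raise DoseValidationError("ld50_gy must be positive")

    def surviving_fraction(self, dose_gy: float) -> float:
        """Fraction of NGFs surviving a total dose, ``2^(-d/LD50)``."""
        if not (dose_gy >= 0):
            raise DoseValidationError(f"dose must be non-negative, got {dose_gy!r}")
        return 2.0 ** (-dose_gy / self.ld50_gy)

    @staticmethod
    def effective_dose(value: float, modality) -> float:
        """Validate a dose and return it in Gy-equivalent terms.

        CGE values already embed the RBE of 1.1, so the conversion is a
        numeric passthrough for both modalities; the modality's
        ``dose_unit`` carries the label for reporting.
        """
        Modality.coerce(modality)
        if not (value >= 0) or not math.isfinite(value):
            raise DoseValidationError(
                f"dose must be a finite non-negative number, got {value!r}"
            )
        return float(value)
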