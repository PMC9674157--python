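"""Prediction of age at premature ovarian insufficiency after radiotherapy.

The core algorithm combines the reserve decline curve with the follicle
survival law:

1. The patient's pre-treatment reserve at age ``a`` on her z-track is
   reduced by the surviving fraction ``S(d)`` for the dose ``d`` to the
   least-affected ovary.
2. The depleted count is mapped back through the healthy curve to an
   *equivalent chronologic age* — the older age at which an unirradiated
   ovary would hold the same count.
3. The patient then ages forward along the healthy decline from that
   equivalent age, so POI (reserve below 1,000 NGFs) arrives at

       poi_age = a + (age_at_threshold(z) - equivalent_age(a, d, z)).

If the dose depresses the reserve to or below the threshold immediately,
POI is declared at the treatment age itself.

The same machinery inverts to the *sterilizing dose*: the dose that drops
the reserve exactly to the threshold, ``LD50 * log2(count / threshold)``.
At z = 0 this is the mean sterilizing dose (sterilizes 50% of subjects);
at z = +1.96 it is the effective sterilizing dose, ESD (97.5% of subjects).

Uncertainty is reported as a grid over the dose triplet (min/mean/max to
the least-affected ovary) and z in {-1, 0, +1}; the z = +/-1 span covers
68% of the natural variation in reserve.  Age 30 is flagged as an
indicative counselling threshold only — it never alters computed values.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CountRangeError, DoseValidationError, ImmediatePoiError
from .radiation import Modality, RadiationResponse
from .reserve import ReserveModel

__all__ = [
    "ExposureScenario",
    "PredictionCell",
    "PoiPrediction",
    "SterilizingDoseCurve",
    "PoiCalculator",
    "COUNSELLING_AGE",
    "Z_GRID",
]

#: indicative fertility-counselling threshold (years); annotation only
COUNSELLING_AGE = 30.0

#: z-scores spanning the 68% natural-variation window
Z_GRID = (-1.0, 0.0, 1.0)

_DOSE_LABELS = ("min", "mean", "max")


@dataclass(frozen=True)
class ExposureScenario:
    """One ovary's exposure: age at treatment plus the dose triplet."""

    age_at_treatment: float
    dose_min: float
    dose_mean: float
    dose_max: float
    modality: Modality = Modality.PHOTON

    def __post_init__(self):
        object.__setattr__(self, "modality", Modality.coerce(self.modality))
        if not (0 <= self.dose_min <= self.dose_mean <= self.dose_max):
            raise DoseValidationError(
                "dose triplet must satisfy 0 <= min <= mean <= max, got "
                f"({self.dose_min}, {self.dose_mean}, {self.dose_max})"
            )

    @property
    def doses(self) -> dict[str, float]:
        return {"min": self.dose_min, "mean": self.dose_mean, "max": self.dose_max}


@dataclass(frozen=True)
class PredictionCell:
    """One (dose-label, z) cell of a prediction grid."""

    dose_label: str
    dose_gy: float
    z: float
    poi_age: float
    years_lost: float
    immediate_poi: bool
    below_counselling_age: bool


@dataclass(frozen=True)
class PoiPrediction:
    """POI ages over the dose-triplet x z grid for one scenario."""

    scenario: ExposureScenario
    cells: tuple[PredictionCell, ...]
    natural_menopause_age: dict[float, float]

    def cell(self, dose_label: str, z: float) -> PredictionCell:
        for c in self.cells:
            if c.dose_label == dose_label and c.z == z:
                return c
        raise KeyError((dose_label, z))

    @property
    def central_poi_age(self) -> float:
        """The calculator's headline number: mean dose at z = 0."""
        return self.cell("mean", 0.0).poi_age

    def window_68(self, dose_label: str = "mean") -> tuple[float, float]:
        """POI-age interval covering 68% of natural reserve variation."""
        return (self.cell(dose_label, -1.0).poi_age,
                self.cell(dose_label, 1.0).poi_age)

    def to_frame(self) -> pd.DataFrame:
        """One row per grid cell."""
        s = self.scenario
        rows = [
            {
                "age_at_treatment": s.age_at_treatment,
                "modality": s.modality.value,
                "dose_unit": s.modality.dose_unit,
                "dose_label": c.dose_label,
                "dose": c.dose_gy,
                "z": c.z,
                "poi_age": c.poi_age,
                "years_lost": c.years_lost,
                "immediate_poi": c.immediate_poi,
                "below_counselling_age": c.below_counselling_age,
            }
            for c in self.cells
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_dict(self) -> dict:
        s = self.scenario
        return {
            "scenario": {
                "age_at_treatment": s.age_at_treatment,
                "dose_min": s.dose_min,
                "dose_mean": s.dose_mean,
                "dose_max": s.dose_max,
                "modality": s.modality.value,
                "dose_unit": s.modality.dose_unit,
            },
            "natural_menopause_age": {str(z): a for z, a in
                                      self.natural_menopause_age.items()},
            "counselling_age": COUNSELLING_AGE,
            "grid": self.to_frame().to_dict(orient="records"),
        }

    def to_json(self, path=None, **kwargs) -> str:
        text = json.dumps(self.to_dict(), indent=2, **kwargs)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


@dataclass(frozen=True)
class SterilizingDoseCurve:
    """Mean (z = 0) and effective (z = +1.96) sterilizing doses vs age."""

    ages: np.ndarray
    mean_dose: np.ndarray
    esd: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"age": self.ages, "mean_sterilizing_dose_gy": self.mean_dose,
             "effective_sterilizing_dose_gy": self.esd}
        )


class PoiCalculator:
    """Ties the reserve model to the radiation response.

    Parameters
    ----------
    model
        The ovarian reserve decline model (defaults to the published fit
    with calibrated dispersion).
    radiation
        Follicle dose-response (default LD50 = 2 Gy).
    """

    def __init__(self, model: ReserveModel | None = None,
                 radiation: RadiationResponse | None = None):
        self.model = model if model is not None else ReserveModel()
        self.radiation = radiation if radiation is not None else RadiationResponse()

    # ------------------------------------------------------------------ #

    def equivalent_age(self, age: float, dose: float, z: float = 0.0) -> float:
        """Healthy-curve age holding the post-irradiation count.

        Raises
        ------
        ImmediatePoiError
            When the surviving count falls below the z-track minimum over
            the age domain, so no equivalent age exists.
        """
        count = self.model.ngf_count(age, z) * self.radiation.surviving_fraction(dose)
        try:
            return self.model.inverse_age(math.log10(count), z)
        except CountRangeError as exc:
            if exc.above:  # pragma: no cover - unreachable for dose >= 0
                raise
            raise ImmediatePoiError(
                f"dose {dose:g} Gy depletes the reserve below the track "
                "minimum; premature ovarian insufficiency is immediate"
            ) from None

    def predict_poi_age(self, age: float, dose: float, z: float = 0.0) -> float:
        """Predicted age at POI; the treatment age itself on immediate POI."""
        menopause = self.model.age_at_threshold(z)
        if age >= menopause:
            warnings.warn(
                f"treatment age {age:g} is at or beyond the z={z:g} track's "
                f"menopause age {menopause:.1f}; POI is immediate",
                stacklevel=2,
            )
            return float(age)
        count = self.model.ngf_count(age, z) * self.radiation.surviving_fraction(dose)
        if count <= self.model.params.poi_threshold:
            return float(age)
        equivalent = self.model.inverse_age(math.log10(count), z)
        return age + (menopause - equivalent)

    def is_immediate_poi(self, age: float, dose: float, z: float = 0.0) -> bool:
        count = self.model.ngf_count(age, z) * self.radiation.surviving_fraction(dose)
        return count <= self.model.params.poi_threshold \
            or age >= self.model.age_at_threshold(z)

    def years_lost(self, age: float, dose: float, z: float = 0.0) -> float:
        """Reproductive lifespan lost to the exposure, in years."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            poi = self.predict_poi_age(age, dose, z)
        return max(self.model.age_at_threshold(z) - poi, 0.0)

    # ------------------------------------------------------------------ #

    def predict_window(self, scenario: ExposureScenario) -> PoiPrediction:
        """Fill the min/mean/max-dose x z in {-1, 0, +1} prediction grid."""
        menopause = {z: self.model.age_at_threshold(z) for z in Z_GRID}
        cells = []
        for label in _DOSE_LABELS:
            dose = scenario.doses[label]
            for z in Z_GRID:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    poi = self.predict_poi_age(scenario.age_at_treatment, dose, z)
                cells.append(PredictionCell(
                    dose_label=label,
                    dose_gy=dose,
                    z=z,
                    poi_age=poi,
                    years_lost=menopause[z] - poi,
                    immediate_poi=self.is_immediate_poi(
                        scenario.age_at_treatment, dose, z),
                    below_counselling_age=poi < COUNSELLING_AGE,
                ))
        return PoiPrediction(
            scenario=scenario, cells=tuple(cells),
            natural_menopause_age=menopause,
        )

    # ------------------------------------------------------------------ #

    def sterilizing_dose(self, age: float, z: float = 0.0) -> float:
        """Dose dropping the reserve at ``age`` exactly to the threshold.

        Closed form ``LD50 * log2(count / threshold)``; returns 0 when the
        reserve is already at or below the threshold.
        """
        count = self.model.ngf_count(age, z)
        threshold = self.model.params.poi_threshold
        if count <= threshold:
            return 0.0
        return self.radiation.ld50_gy * math.log2(count / threshold)

    def sterilizing_dose_curves(self, ages) -> SterilizingDoseCurve:
        """Mean sterilizing dose (z = 0) and ESD (z = +1.96) over an age grid."""
        ages = np.atleast_1d(np.asarray(ages, dtype=float))
        if ages.size == 0:
            raise ValueError("age grid must be non-empty")
        mean = np.array([self.sterilizing_dose(a, 0.0) for a in ages])
        esd = np.array([self.sterilizing_dose(a, 1.96) for a in ages])
        return SterilizingDoseCurve(ages=ages, mean_dose=mean, esd=esd)
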