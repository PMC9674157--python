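"""Per-ovary dose summaries and treatment-plan comparison.

Treatment planning systems report, per delineated ovary, the minimum, mean
and maximum dose of a plan.  This module reads such summaries from a small
CSV/JSON schema, selects the least-affected ovary (the one furthest from
the target, i.e. with the lower mean dose — the basis of the fertility
prediction), and compares competing plans by their predicted POI ages.

CSV schema (comma-separated, UTF-8, header required, doses in decimal Gy)::

    patient_id,plan_label,ovary_side,modality,dose_min_gy,dose_mean_gy,dose_max_gy

A JSON array of objects with the same field names is accepted equivalently.
An absent (e.g. resected) ovary is represented by omitting its row, never
by zero doses.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .engine import PoiCalculator, ExposureScenario, PoiPrediction
from .errors import DosimetryParseError
from .radiation import Modality

__all__ = [
    "OvaryDoseRecord",
    "read_dose_summary",
    "write_dose_summary",
    "least_affected_ovary",
    "compare_plans",
    "CSV_COLUMNS",
]

CSV_COLUMNS = (
    "patient_id", "plan_label", "ovary_side", "modality",
    "dose_min_gy", "dose_mean_gy", "dose_max_gy",
)

_SIDES = ("left", "right")


@dataclass(frozen=True)
class OvaryDoseRecord:
    """Dose summary for one ovary under one treatment plan."""

    patient_id: str
    plan_label: str
    ovary_side: str
    modality: Modality
    dose_min_gy: float
    dose_mean_gy: float
    dose_max_gy: float

    def __post_init__(self):
        object.__setattr__(self, "modality", Modality.coerce(self.modality))
        if self.ovary_side not in _SIDES:
            raise DosimetryParseError(
                f"ovary_side must be one of {_SIDES}, got {self.ovary_side!r}")
        if not (0 <= self.dose_min_gy <= self.dose_mean_gy <= self.dose_max_gy):
            raise DosimetryParseError(
                "doses must satisfy 0 <= min <= mean <= max, got "
                f"({self.dose_min_gy}, {self.dose_mean_gy}, {self.dose_max_gy})"
            )

    def scenario(self, age_at_treatment: float) -> ExposureScenario:
        return ExposureScenario(
            age_at_treatment=age_at_treatment,
            dose_min=self.dose_min_gy,
            dose_mean=self.dose_mean_gy,
            dose_max=self.dose_max_gy,
            modality=self.modality,
        )


def _records_from_frame(df: pd.DataFrame, source) -> list[OvaryDoseRecord]:
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise DosimetryParseError(f"{source}: missing column(s) {missing}")
    records: list[OvaryDoseRecord] = []
    seen: set[tuple] = set()
    for i, row in df.iterrows():
        rowno = int(i) + 2  # 1-based with header line
        doses = {}
        for col in ("dose_min_gy", "dose_mean_gy", "dose_max_gy"):
            try:
                doses[col] = float(row[col])
            except (TypeError, ValueError):
                raise DosimetryParseError(
                    f"{source}, row {rowno}: non-numeric {col} {row[col]!r}"
                ) from None
        try:
            rec = OvaryDoseRecord(
                patient_id=str(row["patient_id"]),
                plan_label=str(row["plan_label"]),
                ovary_side=str(row["ovary_side"]).strip().lower(),
                modality=row["modality"],
                **doses,
            )
        except DosimetryParseError as exc:
            raise DosimetryParseError(f"{source}, row {rowno}: {exc}") from None
        key = (rec.patient_id, rec.plan_label, rec.ovary_side)
        if key in seen:
            raise DosimetryParseError(
                f"{source}, row {rowno}: duplicate record for {key}")
        seen.add(key)
        records.append(rec)
    if not records:
        warnings.warn(f"{source}: no dose records found", stacklevel=3)
    return records


def read_dose_summary(source) -> list[OvaryDoseRecord]:
    """Read a per-ovary dose summary from a CSV or JSON file."""
    path = Path(source)
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        if not isinstance(data, list):
            raise DosimetryParseError(f"{path}: JSON summary must be an array")
        df = pd.DataFrame(data, columns=CSV_COLUMNS if not data else None)
    else:
        df = pd.read_csv(path, dtype={"patient_id": str, "plan_label": str})
    return _records_from_frame(df, path.name)


def write_dose_summary(records, path) -> None:
    """Write records back to the CSV schema (round-trips with the reader)."""
    df = pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "plan_label": r.plan_label,
                "ovary_side": r.ovary_side,
                "modality": r.modality.value,
                "dose_min_gy": r.dose_min_gy,
                "dose_mean_gy": r.dose_mean_gy,
                "dose_max_gy": r.dose_max_gy,
            }
            for r in records
        ],
        columns=list(CSV_COLUMNS),
    )
    df.to_csv(path, index=False)


def least_affected_ovary(records) -> OvaryDoseRecord:
    """The ovary with the lower mean dose (ties: lower max, then left)."""
    records = list(records)
    if not records:
        raise DosimetryParseError("no ovary records supplied")
    if len(records) > 2:
        raise DosimetryParseError(
            f"expected at most 2 ovaries for one patient+plan, got {len(records)}")
    return min(
        records,
        key=lambda r: (r.dose_mean_gy, r.dose_max_gy, _SIDES.index(r.ovary_side)),
    )


def compare_plans(records, age_at_treatment: float,
                  calculator: PoiCalculator | None = None) -> pd.DataFrame:
    """Rank treatment plans for one patient by predicted POI age.

    Returns one row per plan, sorted by descending central (mean-dose,
    z = 0) POI age, with the least-affected ovary, the full prediction
    attached in the ``prediction`` column, and a flag when the central POI
    age falls below the 30-year counselling threshold.
    """
    records = list(records)
    patients = {r.patient_id for r in records}
    if len(patients) != 1:
        raise DosimetryParseError(
            f"plan comparison needs a single patient, got ids {sorted(patients)}")
    plans = sorted({r.plan_label for r in records})
    if len(plans) < 2:
        raise DosimetryParseError(
            f"plan comparison needs at least 2 plans, got {plans}")
    calc = calculator if calculator is not None else PoiCalculator()
    rows = []
    for plan in plans:
        ovary = least_affected_ovary([r for r in records if r.plan_label == plan])
        prediction: PoiPrediction = calc.predict_window(
            ovary.scenario(age_at_treatment))
        central = prediction.cell("mean", 0.0)
        rows.append({
            "plan_label": plan,
            "modality": ovary.modality.value,
            "least_affected_side": ovary.ovary_side,
            "dose_min_gy": ovary.dose_min_gy,
            "dose_mean_gy": ovary.dose_mean_gy,
            "dose_max_gy": ovary.dose_max_gy,
            "poi_age": central.poi_age,
            "years_lost": central.years_lost,
            "immediate_poi": central.immediate_poi,
            "below_counselling_age": central.below_counselling_age,
            "prediction": prediction,
        })
    df = pd.DataFrame(rows).sort_values(
        "poi_age", ascending=False, kind="mergesort").reset_index(drop=True)
    return df
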