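"""Illustrative pediatric case fixtures.

Four representative pediatric radiotherapy cases spanning cranial and
pelvic targets, each with a photon and a proton plan template.  Per-ovary
doses are deliberately left as placeholders: they depend entirely on the
individual treatment plan and must be supplied by the user from their own
planning system before a prediction can be made.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .dosimetry import OvaryDoseRecord
from .radiation import Modality

__all__ = ["CaseFixture", "CASE_FIXTURES", "get_case"]


@dataclass(frozen=True)
class CaseFixture:
    """A case skeleton: age, diagnosis and plan templates without doses."""

    label: str
    age_at_treatment: float
    diagnosis: str
    plan_templates: tuple[str, ...] = ("photon", "proton")

    def dose_records(self, plan_label: str, doses_by_side: dict[str, tuple]) \
            -> list[OvaryDoseRecord]:
        """Materialise user-supplied (min, mean, max) dose triplets.

        ``doses_by_side`` maps 'left'/'right' to a Gy triplet; omit a side
        for an absent ovary.
        """
        if plan_label not in self.plan_templates:
            raise ValueError(
                f"{self.label}: unknown plan {plan_label!r}; "
                f"templates are {self.plan_templates}")
        modality = Modality.coerce(plan_label)
        return [
            OvaryDoseRecord(
                patient_id=self.label,
                plan_label=plan_label,
                ovary_side=side,
                modality=modality,
                dose_min_gy=float(d[0]),
                dose_mean_gy=float(d[1]),
                dose_max_gy=float(d[2]),
            )
            for side, d in sorted(doses_by_side.items())
        ]


CASE_FIXTURES: tuple[CaseFixture, ...] = (
    CaseFixture("case-1", 8.0, "pineoblastoma (craniospinal irradiation)"),
    CaseFixture("case-2", 19.0, "high-risk medulloblastoma (craniospinal irradiation)"),
    CaseFixture("case-3", 16.0, "unresectable pelvic Ewing sarcoma (>8 cm)"),
    CaseFixture("case-4", 3.0, "unresectable pelvic Ewing sarcoma (>8 cm)"),
)


def get_case(label: str) -> CaseFixture:
    for case in CASE_FIXTURES:
        if case.label == label:
            return case
    raise KeyError(
        f"unknown case {label!r}; available: {[c.label for c in CASE_FIXTURES]}")
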