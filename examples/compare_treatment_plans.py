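"""Compare photon vs proton plans for a pelvic-sarcoma case fixture.

The built-in case-4 fixture is a 3-year-old with an unresectable pelvic
Ewing sarcoma.  Per-ovary dose triplets come from the user's treatment
planning system; the illustrative numbers below give the proton plan a
far lower dose to the ovary furthest from the target.
"""

from ovareserve import compare_plans, get_case, render_case_panel

case = get_case("case-4")
print(f"{case.label}: {case.age_at_treatment:g}-year-old, {case.diagnosis}\n")

records = (
    case.dose_records("photon", {"left": (8.0, 12.0, 20.0),
                                 "right": (10.0, 15.0, 25.0)})
    + case.dose_records("proton", {"left": (0.2, 0.5, 1.0),
                                   "right": (0.5, 1.5, 3.0)})
)
table = compare_plans(records, case.age_at_treatment)
print(table.drop(columns=["prediction"]).round(2).to_string(index=False))

path = render_case_panel(table, "case4_panel.png")
print(f"\nPanel written to {path}")
print("Plans are ranked by the central POI age (mean dose to the "
      "least-affected ovary, z = 0). below_counselling_age flags POI "
      "before 30 years, when no natural fertility window is expected.")
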