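"""The POI-prediction algorithm: equivalent age, windows, sterilizing doses."""

import json
import math

import numpy as np
import pandas as pd
import pytest

from ovareserve import (
    DoseValidationError,
    ExposureScenario,
    ImmediatePoiError,
    PoiCalculator,
    RadiationResponse,
)


# --------------------------------------------------------------------- #
# equivalent age

def test_equivalent_age_identity_at_zero_dose(calc):
    assert calc.equivalent_age(5.0, 0.0, 0.0) == pytest.approx(5.0, abs=1e-6)


def test_equivalent_age_halving_dose(calc, grid_oracle):
    """At the LD50 the equivalent age holds half the pre-treatment count."""
    eq = calc.equivalent_age(5.0, 2.0, 0.0)
    target = math.log10(calc.model.ngf_count(5.0, 0.0) / 2)
    assert eq == pytest.approx(grid_oracle.inverse_age(target, 0.0), abs=0.01)
    assert eq > 5.0


def test_equivalent_age_increasing_in_dose(calc):
    eqs = [calc.equivalent_age(5.0, d, 0.0) for d in (0, 1, 2, 4, 8)]
    assert all(a < b for a, b in zip(eqs, eqs[1:]))


def test_equivalent_age_immediate_poi_signal(calc):
    with pytest.raises(ImmediatePoiError):
        calc.equivalent_age(5.0, 100.0, 0.0)


# --------------------------------------------------------------------- #
# POI age prediction

def test_worked_example_one_gray(calc):
    """A 5-year-old receiving 1 Gy: POI near 42, ~8 fertile years lost."""
    poi = calc.predict_poi_age(5.0, 1.0, 0.0)
    assert poi == pytest.approx(42.0, abs=2.0)
    assert calc.years_lost(5.0, 1.0, 0.0) == pytest.approx(8.0, abs=2.0)


def test_worked_example_twelve_gray(calc):
    """The same child at 12 Gy: POI around age 12."""
    assert calc.predict_poi_age(5.0, 12.0, 0.0) == pytest.approx(12.0, abs=2.0)


def test_zero_dose_gives_natural_menopause(calc):
    for age in (3.0, 5.0, 19.0, 40.0):
        assert calc.predict_poi_age(age, 0.0, 0.0) == pytest.approx(
            calc.model.age_at_threshold(0.0), abs=1e-6)


def test_massive_dose_gives_immediate_poi(calc):
    assert calc.predict_poi_age(5.0, 100.0, 0.0) == 5.0
    assert calc.is_immediate_poi(5.0, 100.0, 0.0)
    assert not calc.is_immediate_poi(5.0, 1.0, 0.0)


def test_treatment_after_menopause_warns_and_returns_age(calc):
    late = calc.model.age_at_threshold(0.0) + 1.0
    with pytest.warns(UserWarning, match="immediate"):
        assert calc.predict_poi_age(late, 0.5, 0.0) == late


def test_years_lost_properties(calc):
    assert calc.years_lost(25.0, 0.0, 0.0) == pytest.approx(0.0, abs=1e-9)
    # immediate POI loses the whole remaining natural lifespan
    assert calc.years_lost(5.0, 100.0, 0.0) == pytest.approx(
        calc.model.age_at_threshold(0.0) - 5.0, abs=1e-9)


def test_poi_age_matches_brute_force_oracle(calc, grid_oracle):
    """Solver agrees with the grid-stepping reference on random scenarios."""
    rng = np.random.default_rng(123)
    checked = 0
    while checked < 50:
        age = rng.uniform(0.5, 40.0)
        dose = rng.uniform(0.0, 10.0)
        z = rng.uniform(-1.5, 1.5)
        if calc.is_immediate_poi(age, dose, z):
            continue
        assert abs(calc.predict_poi_age(age, dose, z)
                   - grid_oracle.predict_poi_age(age, dose, z)) < 0.01
        checked += 1


# --------------------------------------------------------------------- #
# prediction windows

def test_window_grid_monotonicities(calc):
    pred = calc.predict_window(ExposureScenario(8.0, 1.0, 3.0, 6.0))
    for label in ("min", "mean", "max"):
        z_ages = [pred.cell(label, z).poi_age for z in (-1.0, 0.0, 1.0)]
        assert z_ages[0] <= z_ages[1] <= z_ages[2]
    for z in (-1.0, 0.0, 1.0):
        assert pred.cell("min", z).poi_age >= pred.cell("mean", z).poi_age \
            >= pred.cell("max", z).poi_age


def test_window_grid_invariants(calc):
    scenario = ExposureScenario(8.0, 1.0, 3.0, 6.0)
    pred = calc.predict_window(scenario)
    for cell in pred.cells:
        assert cell.poi_age >= scenario.age_at_treatment
        assert cell.poi_age <= pred.natural_menopause_age[cell.z] + 1e-9
        assert cell.below_counselling_age == (cell.poi_age < 30.0)
    lo, hi = pred.window_68("mean")
    assert lo <= pred.central_poi_age <= hi


def test_degenerate_triplet_collapses(calc):
    pred = calc.predict_window(ExposureScenario(5.0, 1.0, 1.0, 1.0))
    expected = calc.predict_poi_age(5.0, 1.0, 0.0)
    for label in ("min", "mean", "max"):
        assert pred.cell(label, 0.0).poi_age == pytest.approx(expected)


def test_scenario_dose_ordering_validation():
    with pytest.raises(DoseValidationError):
        ExposureScenario(5.0, 3.0, 2.0, 4.0)
    with pytest.raises(DoseValidationError):
        ExposureScenario(5.0, -1.0, 0.0, 1.0)


# --------------------------------------------------------------------- #
# sterilizing doses

def test_sterilizing_dose_closed_form(calc):
    dose = calc.sterilizing_dose(20.0, 0.0)
    count = calc.model.ngf_count(20.0, 0.0)
    assert dose == pytest.approx(
        calc.radiation.ld50_gy * math.log2(count / 1000.0), rel=1e-12)
    assert dose == pytest.approx(13.4, abs=0.5)


def test_sterilizing_dose_identity_chain(calc):
    """Giving exactly the sterilizing dose triggers POI at the treatment age."""
    for z in (-1.0, 0.0, 1.96):
        for age in range(1, 46, 4):
            dose = calc.sterilizing_dose(float(age), z)
            if dose == 0.0:
                continue
            poi = calc.predict_poi_age(float(age), dose, z)
            assert poi == pytest.approx(age, abs=0.1)


def test_sterilizing_dose_zero_below_threshold(calc):
    late = calc.model.age_at_threshold(0.0) + 0.5
    assert calc.sterilizing_dose(late, 0.0) == 0.0


def test_sterilizing_dose_higher_for_richer_reserve(calc):
    for age in (1.0, 10.0, 25.0, 40.0):
        assert calc.sterilizing_dose(age, 1.96) > calc.sterilizing_dose(age, 0.0)


def test_sterilizing_dose_curves(calc):
    curve = calc.sterilizing_dose_curves(np.arange(0.0, 46.0, 1.0))
    assert np.all(np.diff(curve.mean_dose) < 0)
    assert np.all(np.diff(curve.esd) < 0)
    assert np.all(curve.esd >= curve.mean_dose)
    assert curve.mean_dose[20] == pytest.approx(
        calc.sterilizing_dose(20.0, 0.0), rel=1e-12)
    with pytest.raises(ValueError):
        calc.sterilizing_dose_curves([])


# --------------------------------------------------------------------- #
# serialization

def test_prediction_serialization_round_trip(calc, tmp_path):
    pred = calc.predict_window(ExposureScenario(8.0, 1.0, 3.0, 6.0, "proton"))
    payload = json.loads(pred.to_json(tmp_path / "pred.json"))
    assert payload["scenario"]["dose_unit"] == "CGE"
    assert len(payload["grid"]) == 9
    central = [c for c in payload["grid"]
               if c["dose_label"] == "mean" and c["z"] == 0.0]
    assert central[0]["poi_age"] == pytest.approx(pred.central_poi_age)

    csv_path = tmp_path / "pred.csv"
    pred.to_csv(csv_path)
    frame = pd.read_csv(csv_path)
    pd.testing.assert_frame_equal(frame, pred.to_frame(), check_dtype=False)


def test_ld50_override_shifts_predictions(model):
    tender = PoiCalculator(model, RadiationResponse(ld50_gy=1.0))
    tough = PoiCalculator(model, RadiationResponse(ld50_gy=4.0))
    assert tender.predict_poi_age(5.0, 2.0, 0.0) < tough.predict_poi_age(
        5.0, 2.0, 0.0)
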