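"""Predict the age at POI for one radiotherapy scenario.

An 8-year-old whose least-affected ovary receives 1-6 Gy (min/mean/max of
the plan's dose distribution).  The grid spans the dose triplet and the
z-scores -1/0/+1, i.e. the 68% window of natural variation in ovarian
reserve.
"""

from ovareserve import ExposureScenario, PoiCalculator

calc = PoiCalculator()
scenario = ExposureScenario(age_at_treatment=8.0, dose_min=1.0,
                            dose_mean=3.0, dose_max=6.0, modality="photon")
prediction = calc.predict_window(scenario)

print(prediction.to_frame().to_string(index=False))
lo, hi = prediction.window_68("mean")
print(f"\nCentral estimate (mean dose, average reserve): "
      f"POI at {prediction.central_poi_age:.1f} years")
print(f"68% window at mean dose: {lo:.1f} - {hi:.1f} years")
print("Each row is one dose x z cell: poi_age is the predicted age at "
      "premature ovarian insufficiency, years_lost the reproductive "
      "lifespan forfeited relative to natural menopause on that z-track.")
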