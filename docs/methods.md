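# Methods

## The reserve decline curve

The ovarian reserve model is the Wallace–Kelsey fit of log₁₀ NGF count
against chronologic age: an asymmetric double-Gaussian cumulative (ADC)
peak function

log₁₀ NGF(t) = (A/4) · [1 + erf((t − c + w₁/2)/(√2·w₂))] · [1 − erf((t − c − w₁/2)/(√2·w₃))]

with the five fitted constants A = 5.56 (peak log₁₀-count scale),
c = 25.6 y (peak centre), w₁ = 52.72 y (edge-to-edge span), w₂ = 0.0742 y
(rising-edge width) and w₃ = 24.52 y (falling-edge width). The rising edge
sits at c − w₁/2 ≈ −0.76 y — just before birth — and is so sharp
(w₂ < 0.1 y) that over the model domain [0, 60] years the curve is the
falling limb only: strictly decreasing, which makes every inversion
well-posed.

The algebraic placement of the constants was an open reconstruction
question; the form above is normative because it reproduces every
operational anchor the model is defined by:

| quantity | model | anchor |
|---|---|---|
| NGF at birth | 291,910 | ≈300,000 (±15%) |
| NGF at age 20 | 105,937 | ≈100,000 (±15%) |
| NGF at age 50.5 | 817 | ≈800 (±25%) |
| age crossing 1,000 NGFs | 49.52 y | 49.6 ± 0.5 y |

Ages are chronologic years since birth. A conception-offset coordinate
(shifting the axis by 0.75 y) was tested and rejected: it moves the
menopause crossing to 48.8 y, outside the anchor window. The curve is a
pluggable component: any replacement implementation of `ReserveModel`
must pass the anchor suite in `tests/test_reserve.py`, which is the
model's operational definition.

The POI threshold is 1,000 NGFs. The "about 800 at ages 50–51" anchor is
what the curve *evaluates to* around 50.5 y and is deliberately not the
threshold; the two are consistent because the curve crosses 1,000 slightly
earlier (49.5 y).

## Population dispersion

Between-individual spread of reserve at fixed age is a single
age-independent standard deviation σ of log₁₀ NGF; an individual's track
is log₁₀ NGF(t) + z·σ. No direct estimate of σ exists (reserve cannot be
measured in vivo), but the spread of ages at natural menopause can be
observed: prospective cohorts report SDs near 4 years. σ is therefore
calibrated at model construction so that the z = +1.96 track crosses the
1,000-follicle threshold exactly 1.96 × 4.0 = 7.84 years after the mean
track; with the default curve σ ≈ 0.360. The calibration uses the upper
tail; because the curve is nonlinear the z = −1.96 crossing lands ~8.1
years (not exactly 7.84) below the mean crossing, an asymmetry of ~0.3 y
that we accept rather than force symmetry. `calibration_menopause_sd` is
a config key (default 4.0 y).

A constant-σ log-normal dispersion is an assumption: it implies the
menopause-age distribution inherits its spread purely from the local slope
of the decline curve. Nothing in the package depends on its tails beyond
z = ±1.96.

## Radiation response

NGF killing is single-hit exponential, S(d) = 2^(−d/LD₅₀) with
LD₅₀ = 2 Gy by default — the unique memoryless (split-dose multiplicative)
survival law with the stated LD₅₀. Published estimates put the LD₅₀ at
"less than 2 Gy"; 2 Gy is the conservative choice and the `--ld50`
flag / `ld50` config key accepts lower values. Doses are total physical
doses to the least-affected ovary: fractionation, dose-rate effects and
linear-quadratic repair are intentionally out of scope, matching the
min/mean/max-dose interface of planning systems. Proton CGE values embed
RBE 1.1 and are treated as numerically equal to Gy; only the reporting
unit label differs.

## The POI prediction

For age a, dose d, z-score z:

1. surviving count n = 10^(log₁₀ NGF(a) + z·σ) · S(d);
2. if n ≤ 1,000, POI is immediate: the prediction is a itself (flagged);
3. otherwise the equivalent age a′ solves log₁₀ NGF(a′) + z·σ = log₁₀ n,
   and POI age = a + (t_thr(z) − a′), where t_thr(z) is the z-track's
   threshold-crossing age.

Step 3 assumes the irradiated reserve resumes the healthy decline rate at
the equivalent age. Consequences: POI age equals natural menopause at
d = 0, is non-increasing in d and non-decreasing in z, and can never
exceed the z-track's natural menopause age (the cap is structural, not
clamped). Treatment ages at or beyond the track's menopause age return
immediate POI with a warning rather than an error. Years lost is
t_thr(z) − POI age; on the non-immediate branch it is independent of z,
because the equivalent-age shift cancels the track offset.

The sterilizing dose inverts step 1–2 in closed form:
d* = LD₅₀ · log₂(n₀/1000) for pre-treatment count n₀, returning 0 when
the reserve is already below threshold. z = 0 gives the mean sterilizing
dose (50% of subjects), z = +1.96 the effective sterilizing dose (97.5%),
interpreting "97.5% of subjects" as sufficiency for the +1.96-SD reserve —
consistent with the two-sided 95% band convention.

## Numerical choices

- All inversions run `scipy.optimize.brentq` on the bracket [0, 60] with
  xtol = 1e-9 y; the track is strictly monotone so the root is unique.
  Accuracy is verified in the tests against an independent brute-force
  oracle that tabulates the curve on a 0.001-year grid and inverts by
  nearest-value lookup (agreement < 0.01 y on 50 seeded random
  scenarios).
- Counts are handled in log₁₀ space throughout; the only exponentiations
  are at the reporting boundary.
- Degenerate inputs: negative doses, inverted dose triplets, ages outside
  [0, 60] and unknown modalities raise typed validation errors;
  counts that cannot be inverted distinguish above-maximum from
  below-minimum.
- The 30-year counselling threshold is annotation only; it flags grid
  cells and draws chart lines but never feeds back into any computed
  value.

## Uncertainty reporting

`predict_window` fills a 3 × 3 grid: dose ∈ {min, mean, max to the
least-affected ovary} × z ∈ {−1, 0, +1}. The z = ±1 span is reported as
the 68% window of natural reserve variation; the headline number is the
mean-dose, z = 0 cell. Dose uncertainty and biological uncertainty are
deliberately kept as separate axes rather than convolved — the grid shows
each cell so a counselling discussion can weigh them independently.

## Case fixtures and plan comparison

Four pediatric case skeletons ship with the package (ages 8 and 19 with
craniospinal irradiation for CNS tumours; ages 16 and 3 with pelvic Ewing
sarcoma). They carry ages, diagnoses and photon/proton plan templates
only: per-ovary dose triplets depend entirely on the individual plan and
must be supplied by the user, so the fixtures contain no invented dose
numbers. `compare_plans` selects the least-affected ovary per plan (lower
mean dose; ties broken by lower max, then left side), predicts the full
grid, and ranks plans by central POI age.

Dose summaries use a minimal CSV/JSON schema (patient, plan, side,
modality, min/mean/max Gy) rather than DICOM-RT parsing; the model
consumes exactly a dose triplet, and plan-system export of these
statistics is universal. The historical config key `exponent` maps to the
rising-edge width w₂ (the constant is dimensionally a width in this
parameterisation; the key name is kept for config compatibility).

## Limitations

- Chemotherapy gonadotoxicity is additive but unquantified; all fertile
  window predictions are upper limits.
- The dispersion model is calibrated to menopause-age SD, not measured
  reserve variance; the 68% window is a modelling construct.
- Fractionation effects are ignored; for highly fractionated or
  low-dose-rate regimens the single-hit law may overestimate kill.
- The decline curve is a population fit from histologic studies; it does
  not capture individual trajectories, pathology (e.g. Turner syndrome)
  or measurement of reserve by biomarkers.
- Predictions outside the fitted age domain [0, 60] are refused rather
  than extrapolated.
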