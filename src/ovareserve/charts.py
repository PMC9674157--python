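"""Calculator-style charts.

Pure views over the engine: rendering never mutates model state, and the
plotted series are exactly the engine's outputs.  Files are written in
whatever format the output path's extension selects (PNG, SVG, ...).
"""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .engine import COUNSELLING_AGE, PoiCalculator

__all__ = [
    "render_dose_response_chart",
    "render_esd_chart",
    "render_case_panel",
]


def _finish(fig, output_path) -> Path:
    output_path = Path(output_path)
    output_path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(output_path)
    plt.close(fig)
    return output_path


def render_dose_response_chart(ages, doses, output_path,
                               calculator: PoiCalculator | None = None) -> Path:
    """Predicted POI age vs age at treatment, one curve per dose.

    The dashed horizontal line marks the 30-year indicative counselling
    threshold; the diagonal marks immediate POI (POI age = treatment age).
    """
    calc = calculator if calculator is not None else PoiCalculator()
    ages = np.atleast_1d(np.asarray(ages, dtype=float))
    doses = np.atleast_1d(np.asarray(doses, dtype=float))
    fig, ax = plt.subplots(figsize=(7, 5))
    for dose in doses:
        poi = [calc.predict_poi_age(a, dose, 0.0) for a in ages]
        ax.plot(ages, poi, marker="o" if ages.size == 1 else None,
                label=f"{dose:g} Gy")
    ax.plot(ages, ages, color="0.6", lw=0.8, ls=":", label="immediate POI")
    ax.axhline(COUNSELLING_AGE, color="crimson", ls="--", lw=1,
               label=f"counselling threshold ({COUNSELLING_AGE:g} y)")
    ax.set_xlabel("Age at radiotherapy (years)")
    ax.set_ylabel("Predicted age at POI (years)")
    ax.set_title("Predicted age at POI by dose to the least-affected ovary")
    ax.legend(fontsize=8)
    return _finish(fig, output_path)


def render_esd_chart(age_grid, output_path,
                     calculator: PoiCalculator | None = None) -> Path:
    """Mean and effective sterilizing dose curves over an age grid."""
    calc = calculator if calculator is not None else PoiCalculator()
    curve = calc.sterilizing_dose_curves(age_grid)
    fig, ax = plt.subplots(figsize=(7, 5))
    ax.plot(curve.ages, curve.mean_dose, color="tab:blue",
            label="mean sterilizing dose (50% of subjects)")
    ax.plot(curve.ages, curve.esd, color="tab:red",
            label="effective sterilizing dose (97.5% of subjects)")
    ax.set_xlabel("Age at treatment (years)")
    ax.set_ylabel("Dose to the ovary (Gy)")
    ax.set_title("Sterilizing doses of radiation to the human ovary")
    ax.legend(fontsize=8)
    return _finish(fig, output_path)


def render_case_panel(comparison: pd.DataFrame, output_path) -> Path:
    """Per-plan POI windows from a plan-comparison table.

    Each plan gets a dot at the central (mean-dose, z = 0) POI age, a bar
    across the min-max dose range, a shaded band across the z = +/-1 (68%)
    window, and the 30-year counselling line.
    """
    if "prediction" not in comparison.columns or len(comparison) == 0:
        raise ValueError("comparison table must carry a 'prediction' column")
    fig, ax = plt.subplots(figsize=(7, 1.2 + 1.1 * len(comparison)))
    for y, (_, row) in enumerate(comparison.iterrows()):
        pred = row["prediction"]
        lo68, hi68 = pred.window_68("mean")
        ax.barh(y, hi68 - lo68, left=lo68, height=0.55, color="tab:blue",
                alpha=0.25, label="68% window" if y == 0 else None)
        # dose range at z = 0: max dose gives the earlier POI age
        d_lo = pred.cell("max", 0.0).poi_age
        d_hi = pred.cell("min", 0.0).poi_age
        ax.plot([d_lo, d_hi], [y, y], color="k", lw=2,
                label="min-max dose range" if y == 0 else None)
        ax.plot(pred.central_poi_age, y, "o", color="tab:orange", ms=8,
                label="mean dose (z = 0)" if y == 0 else None)
    ax.axvline(COUNSELLING_AGE, color="crimson", ls="--", lw=1,
               label=f"counselling threshold ({COUNSELLING_AGE:g} y)")
    ax.set_yticks(range(len(comparison)))
    ax.set_yticklabels(comparison["plan_label"])
    ax.set_xlabel("Predicted age at POI (years)")
    ax.set_title("Treatment-plan comparison")
    ax.legend(fontsize=8, loc="lower right")
    fig.tight_layout()
    return _finish(fig, output_path)
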