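"""Key-value configuration for the model constants.

A single JSON file can override any of the documented keys::

    amplitude                  peak log10-count scale (default 5.56)
    center_age                 ADC peak centre, years (25.6)
    width_1                    full edge-to-edge span, years (52.72)
    exponent                   rising-edge width, years (0.0742); the key
                               name is historical — see docs/methods.md
    width_2                    falling-edge width, years (24.52)
    age_min, age_max           model domain, years (0, 60)
    poi_threshold              follicle count defining POI (1000)
    calibration_menopause_sd   menopause-age SD used to calibrate the
                               log10 dispersion, years (4.0)
    ld50                       follicle median lethal dose, Gy (2.0)
"""

from __future__ import annotations

import json
from pathlib import Path

from .engine import PoiCalculator
from .radiation import RadiationResponse
from .reserve import ReserveCurveParams, ReserveModel

__all__ = ["load_config", "build_calculator"]

_PARAM_KEYS = {
    "amplitude": "amplitude",
    "center_age": "center_age",
    "width_1": "span",
    "exponent": "rise_width",
    "width_2": "fall_width",
    "age_min": "age_min",
    "age_max": "age_max",
    "poi_threshold": "poi_threshold",
}
_OTHER_KEYS = {"calibration_menopause_sd", "ld50"}


def load_config(path) -> dict:
    """Read and validate a JSON config file; returns the raw mapping."""
    data = json.loads(Path(path).read_text())
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must contain a JSON object")
    unknown = set(data) - set(_PARAM_KEYS) - _OTHER_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return data


def build_calculator(config: dict | None = None, *,
                     ld50: float | None = None) -> PoiCalculator:
    """Build a :class:`PoiCalculator` from a config mapping.

    ``ld50`` (e.g. from a command-line flag) overrides the config value.
    """
    config = dict(config or {})
    params = ReserveCurveParams(**{
        _PARAM_KEYS[k]: float(v) for k, v in config.items() if k in _PARAM_KEYS
    })
    model = ReserveModel(
        params,
        calibration_menopause_sd=float(config.get("calibration_menopause_sd", 4.0)),
    )
    if ld50 is None:
        ld50 = float(config.get("ld50", 2.0))
    return PoiCalculator(model, RadiationResponse(ld50_gy=float(ld50)))
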