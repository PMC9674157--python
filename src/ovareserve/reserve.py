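"""Age-related decline of the human ovarian reserve.

The ovarian reserve is the population of non-growing follicles (NGFs) a
woman is born with; it declines monotonically from roughly 300,000 at birth
to below 1,000 around the natural menopause.  The decline is modelled on a
log10 scale by the Wallace-Kelsey asymmetric double-Gaussian cumulative
(ADC) curve,

    log10 NGF(age) = (A/4) * [1 + erf((age - c + w_rise_span/2) / (sqrt(2) w_rise))]
                           * [1 - erf((age - c - w_rise_span/2) / (sqrt(2) w_fall))]

a peak function whose steep rising edge sits just before birth, so that over
the chronologic-age domain [0, 60] the curve is strictly decreasing.

Individual variation is carried by a single age-independent standard
deviation of log10 NGF (``sigma_log10``); an individual's track is
``log10 NGF(age) + z * sigma_log10`` for her z-score.  The dispersion is
calibrated so the spread of ages at which tracks cross the 1,000-follicle
menopause threshold reproduces the observed standard deviation of age at
natural menopause (about 4 years in prospective cohorts).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import erf

from .errors import AgeDomainError, CountRangeError

__all__ = [
    "ReserveCurveParams",
    "PopulationDispersion",
    "ReserveModel",
    "DEFAULT_PARAMS",
]

_SQRT2 = math.sqrt(2.0)


@dataclass(frozen=True)
class ReserveCurveParams:
    """The five fitted ADC constants plus domain and threshold settings.

    Parameters
    ----------
    amplitude
        Peak log10 follicle count scale ``A`` (dimensionless, log10 counts).
    center_age
        Centre of the ADC peak ``c`` in years.
    span
        Full width ``w1`` between the rising and falling edges, years.
    rise_width
        Width of the (pre-birth) rising edge ``w2``, years.
    fall_width
        Width of the falling edge ``w3`` governing the decline to
        menopause, years.
    age_min, age_max
        Closed chronologic-age domain of validity, years.
    poi_threshold
        Follicle count below which premature ovarian insufficiency /
        menopause is deemed to occur.
    """

    amplitude: float = 5.56
    center_age: float = 25.6
    span: float = 52.72
    rise_width: float = 0.0742
    fall_width: float = 24.52
    age_min: float = 0.0
    age_max: float = 60.0
    poi_threshold: float = 1000.0

    def __post_init__(self):
        if self.amplitude <= 0 or self.span <= 0 or self.rise_width <= 0 \
                or self.fall_width <= 0:
            raise ValueError("curve shape parameters must be positive")
        if not self.age_min < self.age_max:
            raise ValueError("age_min must be below age_max")
        if self.poi_threshold <= 0:
            raise ValueError("poi_threshold must be positive")


DEFAULT_PARAMS = ReserveCurveParams()


@dataclass(frozen=True)
class PopulationDispersion:
    """Between-individual spread of log10 reserve at fixed age.

    ``sigma_log10`` is the standard deviation of log10 NGF count across
    individuals of the same age; ``calibration_menopause_sd`` records the
    menopause-age standard deviation (years) it was calibrated against.
    """

    sigma_log10: float
    calibration_menopause_sd: float = 4.0

    def __post_init__(self):
        if self.sigma_log10 <= 0:
            raise ValueError("sigma_log10 must be positive")


class ReserveModel:
    """The NGF decline curve, its inversion, and the z-score tracks.

    Parameters
    ----------
    params
        Curve constants and domain; defaults to the published fit.
    dispersion
        Population dispersion.  When omitted it is calibrated so that the
        z = +1.96 track crosses the menopause threshold
        ``1.96 * calibration_menopause_sd`` years later than the mean track.
    calibration_menopause_sd
        Menopause-age SD (years) used for that calibration when
        ``dispersion`` is omitted.
    """

    def __init__(
        self,
        params: ReserveCurveParams = DEFAULT_PARAMS,
        dispersion: PopulationDispersion | None = None,
        *,
        calibration_menopause_sd: float = 4.0,
    ):
        self.params = params
        if dispersion is None:
            dispersion = self._calibrate_dispersion(calibration_menopause_sd)
        self.dispersion = dispersion

    # ------------------------------------------------------------------ #
    # the curve

    def _log10_curve(self, age):
        """ADC curve value; accepts scalars or arrays, no domain check."""
        p = self.params
        a = np.asarray(age, dtype=float)
        rising = 1.0 + erf((a - p.center_age + p.span / 2.0) / (_SQRT2 * p.rise_width))
        falling = 1.0 - erf((a - p.center_age - p.span / 2.0) / (_SQRT2 * p.fall_width))
        return (p.amplitude / 4.0) * rising * falling

    def _check_age(self, age: float) -> float:
        p = self.params
        if not (p.age_min <= age <= p.age_max) or not math.isfinite(age):
            raise AgeDomainError(
                f"age {age!r} outside the model domain "
                f"[{p.age_min:g}, {p.age_max:g}] years"
            )
        return float(age)

    def log10_ngf(self, age: float):
        """log10 NGF count on the population-average (z = 0) track.

        Strictly decreasing in age over the domain.  Array input is
        supported; domain checking is element-wise.
        """
        a = np.asarray(age, dtype=float)
        if a.ndim == 0:
            return float(self._log10_curve(self._check_age(float(a))))
        p = self.params
        if np.any((a < p.age_min) | (a > p.age_max) | ~np.isfinite(a)):
            raise AgeDomainError(
                f"ages outside the model domain [{p.age_min:g}, {p.age_max:g}] years"
            )
        return self._log10_curve(a)

    def ngf_count(self, age: float, z: float = 0.0) -> float:
        """NGF count at ``age`` for an individual with z-score ``z``."""
        if not math.isfinite(z):
            raise ValueError("z must be finite")
        return float(10.0 ** (self.log10_ngf(age) + z * self.dispersion.sigma_log10))

    # ------------------------------------------------------------------ #
    # inversion

    def inverse_age(self, log10_count: float, z: float = 0.0) -> float:
        """Age at which the z-track holds ``log10_count`` (log10 NGFs).

        The track is strictly decreasing, so the age is unique; solved by
        bracketed root finding on the age domain to well below 1e-6 years.

        Raises
        ------
        CountRangeError
            If the count lies above the track value at the youngest age or
            below its value at the oldest age.
        """
        p = self.params
        offset = z * self.dispersion.sigma_log10
        hi = self._log10_curve(p.age_min) + offset
        lo = self._log10_curve(p.age_max) + offset
        if log10_count > hi:
            raise CountRangeError(
                f"log10 count {log10_count:.4f} exceeds the track maximum "
                f"{hi:.4f} at age {p.age_min:g}", above=True,
            )
        if log10_count < lo:
            raise CountRangeError(
                f"log10 count {log10_count:.4f} is below the track minimum "
                f"{lo:.4f} at age {p.age_max:g}", above=False,
            )
        return brentq(
            lambda a: self._log10_curve(a) + offset - log10_count,
            p.age_min, p.age_max, xtol=1e-9,
        )

    def age_at_threshold(self, z: float = 0.0) -> float:
        """Age at which the z-track falls to the POI threshold.

        For z = 0 this is the model's predicted average age at natural
        menopause (about 49.5 years with the default constants).
        """
        return self.inverse_age(math.log10(self.params.poi_threshold), z)

    # ------------------------------------------------------------------ #
    # dispersion calibration

    def _calibrate_dispersion(self, menopause_sd: float) -> PopulationDispersion:
        # choose sigma so that the +1.96 track reaches threshold exactly
        # 1.96 * menopause_sd years after the mean track does
        if menopause_sd <= 0:
            raise ValueError("calibration_menopause_sd must be positive")
        thr = math.log10(self.params.poi_threshold)
        a0 = brentq(
            lambda a: self._log10_curve(a) - thr,
            self.params.age_min, self.params.age_max, xtol=1e-9,
        )
        a_hi = a0 + 1.96 * menopause_sd
        if a_hi > self.params.age_max:
            raise ValueError(
                "menopause SD too large: the +1.96 crossing age "
                f"{a_hi:.1f} exceeds the domain maximum"
            )
        sigma = (thr - float(self._log10_curve(a_hi))) / 1.96
        return PopulationDispersion(sigma, calibration_menopause_sd=menopause_sd)
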