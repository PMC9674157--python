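"""Exception hierarchy for the ovarian-reserve calculator."""


class OvaReserveError(Exception):
    """Base class for all package errors."""


class AgeDomainError(OvaReserveError, ValueError):
    """An age falls outside the model's valid age interval."""


class CountRangeError(OvaReserveError, ValueError):
    """A follicle count cannot be inverted on the requested track.

    ``above`` is True when the count exceeds the track maximum (the count
    at the youngest age of the domain), False when it lies below the track
    minimum (the count at the oldest age).
    """

    def __init__(self, message: str, *, above: bool):
        super().__init__(message)
        self.above = above


class ImmediatePoiError(OvaReserveError):
    """The post-irradiation reserve is too depleted to map to an age.

    Signals the immediate premature-ovarian-insufficiency condition: the
    surviving follicle population is at or below the level the track reaches
    at the end of the age domain, so no equivalent chronologic age exists.
    """


class DoseValidationError(OvaReserveError, ValueError):
    """A dose value or dose ordering constraint is invalid."""


class DosimetryParseError(OvaReserveError, ValueError):
    """A per-ovary dose-summary table failed validation; cites the row."""
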