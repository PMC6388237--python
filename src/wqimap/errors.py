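"""Exception hierarchy for wqimap.

All package-specific failures derive from :class:`WqimapError` so callers
can catch one base class at pipeline boundaries.
"""


class WqimapError(Exception):
    """Base class for all wqimap errors."""


class InvalidStandardError(WqimapError):
    """A regulatory limit is missing, nonpositive, or otherwise unusable."""


class InvalidMeasurementError(WqimapError):
    """A measured value violates its physical domain (negative concentration,
    pH outside (0, 14), negative microbial count)."""


class UnknownIndicatorError(WqimapError):
    """A measurement refers to an indicator with no standards entry."""


class EmptyRecordError(WqimapError):
    """A record carries no usable measurements."""


class InsufficientDataError(WqimapError):
    """Too few samples, pairs, or bins for the requested operation."""


class NearSingularSystemError(WqimapError):
    """The kriging system is singular or near-singular (e.g. duplicate
    sample locations or an all-zero variogram)."""


class DegenerateDataError(WqimapError):
    """Input data leave a statistic undefined (zero denominator)."""


class ConfigError(WqimapError):
    """An invalid configuration value."""
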