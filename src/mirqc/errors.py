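"""Exception hierarchy for mirqc.

Everything raised on purpose derives from :class:`MirQCError` so callers can
catch pipeline failures with a single except clause while still letting
programming errors (plain TypeError etc.) propagate.
"""


class MirQCError(Exception):
    """Base class for all mirqc errors."""


class ConfigurationError(MirQCError, ValueError):
    """Invalid configuration (fractions not summing to 1, negative SDs, ...)."""


class DimensionError(MirQCError, ValueError):
    """Array shapes incompatible with the requested operation."""


class CoverageError(MirQCError, ValueError):
    """Piecewise standardization segments do not cover the spectral grid."""


class SchemaError(MirQCError, ValueError):
    """A record table lacks required columns."""


class AlignmentError(MirQCError, ValueError):
    """Sample identifiers of two objects do not match."""


class FitError(MirQCError, RuntimeError):
    """Model fitting failed (too few samples, rank deficiency, ...)."""


class DegenerateInputError(MirQCError, ValueError):
    """Input carries no usable variation (e.g. zero total spectral variance)."""


class NearSingularCovarianceError(MirQCError, RuntimeError):
    """Score covariance is numerically singular; lower the variance target."""


class EmptyInputError(MirQCError, ValueError):
    """An operation received zero records."""


class UndefinedStatisticError(MirQCError, ValueError):
    """The requested statistic is undefined for this input (e.g. zero loss)."""


class ParseError(MirQCError, ValueError):
    """A file could not be parsed; the message points at the offending cell."""
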