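"""Exception hierarchy for the mwacool pipeline.

Every error raised by the package derives from :class:`MwacoolError`, so
callers (and the CLI) can catch pipeline failures without masking genuine
programming errors.
"""


class MwacoolError(Exception):
    """Base class for all mwacool errors."""


class ConfigurationError(MwacoolError):
    """An invalid study/phantom configuration (violated invariant is named)."""


class ParameterError(MwacoolError):
    """An operation was called with an out-of-range parameter."""


class GeometryError(MwacoolError):
    """A polygon/point input violates a geometric precondition."""


class DataError(MwacoolError):
    """Derived per-slice or per-stack data violate an invariant."""


class MeasurementError(MwacoolError):
    """Too little data to perform a measurement (e.g. < 2 slices)."""


class FittingError(MwacoolError):
    """A local regression window has too few points to fit."""


class LoadError(MwacoolError):
    """A slice table or report file failed validation on load."""
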