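"""Exception hierarchy.

Every error raised by this package derives from :class:`CranioShapeError`
so callers can catch the whole family at a pipeline boundary.
"""


class CranioShapeError(Exception):
    """Base class for all package errors."""


class FormatError(CranioShapeError):
    """A file could not be parsed as the requested format."""


class SchemaError(CranioShapeError):
    """A structured document (JSON landmarks, report) misses required fields."""


class InsufficientDataError(CranioShapeError):
    """Too few points/samples for the requested computation."""


class GeometryError(CranioShapeError):
    """Degenerate geometric configuration (collinear landmarks, origin outside slice, ...)."""


class FitError(CranioShapeError):
    """Least-squares fit produced a non-ellipsoidal or degenerate solution."""


class NumericError(CranioShapeError):
    """An iterative numeric routine failed to converge."""


class IllConditionedError(CranioShapeError):
    """Design matrix condition number exceeds the safe threshold."""


class CoverageError(CranioShapeError):
    """Point cloud does not cover the region needed by a measurement."""


class SampleSizeError(CranioShapeError):
    """A statistical group is too small."""


class DegenerateDataError(CranioShapeError):
    """Statistical input with zero variance where variance is required."""
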