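"""Exception hierarchy for the petlimit pipeline.

Every stage raises a subclass of :class:`PetLimitError` so callers can
distinguish pipeline failures from programming errors.
"""


class PetLimitError(Exception):
    """Base class for all petlimit errors."""


class ValidationError(PetLimitError, ValueError):
    """An input value violates a documented invariant."""


class CapacityError(ValidationError):
    """More wells requested than the plate layout can hold."""


class CoverageError(ValidationError):
    """A well (or VOI) falls outside the image grid."""


class GeometryError(ValidationError):
    """A VOI has empty membership or lies outside the image."""


class ReproducibilityError(ValidationError):
    """A stochastic operation was invoked without a seed."""


class DegenerateStatisticsError(PetLimitError):
    """Too few voxels/observations to compute the requested statistic."""


class UndefinedCNRError(PetLimitError):
    """CNR requested with zero background standard deviation."""


class SingularFitError(PetLimitError):
    """Regression input is degenerate (n too small or predictor constant)."""


class NoFiniteLLDError(PetLimitError):
    """The regression slope does not allow a finite, positive detection limit."""


class InestimableError(PetLimitError):
    """A model fit is not estimable (e.g. single-class logistic input)."""


class UndefinedRCError(ValidationError):
    """Recovery coefficient requested with non-positive known activity."""


class SchemaError(PetLimitError):
    """A table or file is missing required columns or malformed."""
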