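"""Exception hierarchy for gaitgen.

All gaitgen errors derive from :class:`GaitgenError` so callers can catch
pipeline failures with a single except clause while still distinguishing
geometry problems from data problems.
"""


class GaitgenError(Exception):
    """Base class for all gaitgen errors."""


class GeometryError(GaitgenError):
    """Degenerate marker geometry (collinear/coincident markers, singular frame)."""


class AlignmentError(GaitgenError):
    """Series that should share a time base or grid do not."""


class InsufficientDataError(GaitgenError):
    """Not enough strides/contacts/samples to perform the operation."""


class CoverageError(GaitgenError):
    """A series does not cover the time interval required for segmentation."""


class WindowError(GaitgenError):
    """An analysis window (e.g. foot flat) is empty or outside the stride."""


class SchemaError(GaitgenError):
    """Missing or malformed columns, metadata fields, or config keys."""


class EstimationError(GaitgenError):
    """A statistical estimate could not be formed (e.g. every CV fold skipped)."""


class OrderingError(GaitgenError):
    """Predicted gait-event timings violate the event ordering beyond repair."""


class UndefinedCorrelationError(GaitgenError):
    """Pearson correlation requested for a zero-variance series."""


class ExtrapolationWarning(UserWarning):
    """Prediction requested outside the training range of a regression model."""


class RankDeficiencyWarning(UserWarning):
    """A cross-validation fold had a rank-deficient design matrix and was skipped."""


class PowerWarning(UserWarning):
    """A statistical test was run with too few subjects to be informative."""
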