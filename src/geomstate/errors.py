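"""Exception types shared across the pipeline."""


class GeomstateError(Exception):
    """Base class for all package errors."""


class InvalidSpecError(GeomstateError, ValueError):
    """A design / generator specification is internally inconsistent."""


class InvalidParameterError(GeomstateError, ValueError):
    """A numeric parameter is out of its admissible range."""


class MissingConditionError(GeomstateError, ValueError):
    """A required condition label has no trials (or no planted coordinates)."""


class DegenerateInputError(GeomstateError, ValueError):
    """Too few conditions/vertices for the requested operation."""


class IncompatibleSpaceError(GeomstateError, ValueError):
    """Channel sets (or window grids) of two objects do not match."""


class InvalidPolygonError(GeomstateError, ValueError):
    """Fewer than three vertices."""


class ConfigurationError(GeomstateError, ValueError):
    """Unknown label-order convention, malformed config, family mismatch."""


class SplitCoverageError(GeomstateError, ValueError):
    """A behavioral split leaves a condition without trials."""


class GeometryPlacementError(GeomstateError, ValueError):
    """A planted ROI does not fit inside the volume grid."""


class InvalidMaskError(GeomstateError, ValueError):
    """Empty brain mask or empty cluster mask."""


class InsufficientDataError(GeomstateError, ValueError):
    """Not enough epochs / subjects / trials for the estimator."""


class InvalidFrequencyError(GeomstateError, ValueError):
    """Requested frequency not resolvable at the given sampling rate."""


class InvalidWindowError(GeomstateError, ValueError):
    """A time window falls outside the epoch."""


class InvalidRoiError(GeomstateError, ValueError):
    """ROI empty or too small for a multivariate statistic."""
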