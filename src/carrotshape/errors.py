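"""Exception hierarchy for the carrotshape pipeline.

Every stage raises a subclass of :class:`CarrotShapeError`, so callers can
catch one type at the pipeline boundary while tests assert on the specific
failure mode.
"""


class CarrotShapeError(Exception):
    """Base class for all carrotshape errors."""


class MalformedImageError(CarrotShapeError):
    """Input image is not an H x W x 3 8-bit RGB array."""


class DegenerateImageError(CarrotShapeError):
    """Intensity plane carries no contrast, so no threshold separates
    foreground from background."""


class NoObjectError(CarrotShapeError):
    """A mask contains no foreground pixels where an object is required."""


class TooSmallError(CarrotShapeError):
    """Silhouette is too short along its principal axis to partition."""


class InvalidSpecError(CarrotShapeError):
    """A silhouette spec violates its class-consistency invariants."""


class InvalidConfigError(CarrotShapeError):
    """A generator or pipeline configuration is unusable (empty ranges,
    missing paths, bad weights)."""


class SingularCovarianceError(CarrotShapeError):
    """A class covariance matrix is singular and no ridge was requested.

    ``features`` names the columns implicated in the rank deficiency.
    """

    def __init__(self, message, features=()):
        super().__init__(message)
        self.features = tuple(features)


class SchemaError(CarrotShapeError):
    """Feature columns of the data do not match the fitted model."""


class StratificationError(CarrotShapeError):
    """A cross-validation scheme cannot produce folds with every class
    represented."""


class NoDataError(CarrotShapeError):
    """An evaluation was requested on an empty table."""
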