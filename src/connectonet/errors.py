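"""Exception hierarchy shared across the package."""


class ConnectonetError(Exception):
    """Base class for all package-specific errors."""


class InvalidSampleSizeError(ConnectonetError):
    """A test was requested on fewer observations than it needs."""


class DegenerateVarianceError(ConnectonetError):
    """Pooled variance is zero while the group means differ."""


class LengthMismatchError(ConnectonetError):
    """Paired vectors have different lengths."""


class EmptyNullError(ConnectonetError):
    """An empirical p-value was requested against an empty null sample."""


class NotPositiveDefiniteError(ConnectonetError):
    """A target correlation matrix could not be repaired to positive definite."""


class EdgeOutOfRangeError(ConnectonetError):
    """A planted edge references a region outside the matrix."""


class TooFewVolumesError(ConnectonetError):
    """A time series has too few volumes for the requested operation."""


class InvalidBandError(ConnectonetError):
    """Band-pass edges are outside (0, Nyquist] or out of order."""


class DimensionMismatchError(ConnectonetError):
    """Regressor or motion rows do not match the series length."""


class AllFramesCensoredError(ConnectonetError):
    """Scrubbing left fewer frames than the minimum needed for correlation."""


class ZeroVarianceChannelError(ConnectonetError):
    """A region's time course is constant, so Pearson r is undefined."""


class DesignMismatchError(ConnectonetError):
    """Group lists are incompatible with the requested paired/unpaired design."""


class InsufficientSubjectsError(ConnectonetError):
    """Fewer than two subjects per group (or class)."""


class InvalidThresholdError(ConnectonetError):
    """A p-value threshold outside (0, 1)."""


class NotSymmetricError(ConnectonetError):
    """A matrix expected to be symmetric is not."""


class SingleClassError(ConnectonetError):
    """Feature selection needs both classes present."""


class EmptyClassError(ConnectonetError):
    """ROC analysis needs at least one value per class."""


class ManifestError(ConnectonetError):
    """The subject manifest is malformed or inconsistent."""
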