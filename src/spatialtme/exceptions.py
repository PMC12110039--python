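"""Exception types raised across the package.

All inherit from ValueError so callers that do not care about the precise
failure mode can catch a single base class.
"""


class SpatialTMEError(ValueError):
    """Base class for all package-specific errors."""


class InsufficientProbesError(SpatialTMEError):
    """Fewer than two negative probes available for an AOI."""


class DegenerateAOIError(SpatialTMEError):
    """An AOI has a zero 75th-percentile count and cannot be Q3-scaled."""


class EmptyInputError(SpatialTMEError):
    """An operation received an empty matrix or table."""


class InsufficientOverlapError(SpatialTMEError):
    """Too few genes shared between expression matrix and signature."""


class EmptyGroupError(SpatialTMEError):
    """A group-comparison stratum contains no observations."""


class SchemaError(SpatialTMEError):
    """A required column is missing from an input table."""


class DegenerateCompartmentError(SpatialTMEError):
    """A compartment has zero area."""


class EmptyClassError(SpatialTMEError):
    """A phenotype class needed for a distance metric has no cells."""


class UncomputableRatioError(SpatialTMEError):
    """Every denominator in a group is zero; the ratio is undefined."""


class DegenerateSplitError(SpatialTMEError):
    """Dichotomization rule cannot split identical values."""


class EmptyStratumError(SpatialTMEError):
    """A survival stratum contains no subjects."""


class EmptySetError(SpatialTMEError):
    """A gene set has no overlap with the expression matrix."""


class InsufficientDataError(SpatialTMEError):
    """Fewer paired observations than the method requires."""


class JoinError(SpatialTMEError):
    """No matched samples across the two platforms."""
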