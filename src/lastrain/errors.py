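"""Structured exceptions raised by the analysis stages."""


class LastrainError(Exception):
    """Base class for all package errors."""


class InvalidGeometryError(LastrainError):
    """Degenerate contour geometry: zero length, zero radius, self-intersection."""


class InvalidInputError(LastrainError):
    """Inputs violate a precondition (non-positive sizes, non-monotone times...)."""


class PhaseDetectionError(LastrainError):
    """The strain curve has no usable reservoir peak / phase structure."""


class MissingLandmarkError(LastrainError):
    """Mitral annulus landmarks absent where required."""


class DegenerateAxisError(LastrainError):
    """LA centre of mass coincides with the MV centre; the MV axis is undefined."""


class ClusteringDegenerateError(LastrainError):
    """Too few distinct intensities inside the mask to form k clusters."""


class InsufficientSampleError(LastrainError):
    """Statistical routine called with too few observations."""


class ConfigurationError(LastrainError):
    """Inconsistent pipeline configuration (segment counts, missing paths...)."""
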