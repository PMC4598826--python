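"""Exception hierarchy shared across the package."""


class SerialRegError(Exception):
    """Base class for all package errors."""


class NoSectionsError(SerialRegError):
    """Raised when a stack source contains no readable sections."""


class DecodeError(SerialRegError):
    """Raised when a section file cannot be decoded."""


class WriteError(SerialRegError):
    """Raised when a stack cannot be written."""


class DomainError(SerialRegError):
    """A point or field evaluated outside its image domain."""


class ShapeError(SerialRegError):
    """Two images that must share a shape do not."""


class EmptyHistogramError(SerialRegError):
    """All-zero histogram passed to the saturation-bound search."""


class DegenerateStainError(SerialRegError):
    """Stain vectors are parallel or the stain matrix is singular."""


class InsufficientExtentError(SerialRegError):
    """Image too small for keypoint detection."""


class NoFeaturesError(SerialRegError):
    """Keypoint list empty where matches are required."""


class CoarseRegistrationError(SerialRegError):
    """RANSAC could not reach a geometric consensus."""


class OptimizationDivergedError(SerialRegError):
    """Elastic energy became non-finite."""


class ConfigError(SerialRegError):
    """Invalid run configuration."""
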