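"""Exception types raised across the package."""


class SpineVBError(Exception):
    """Base class for all package-specific errors."""


class VolumeFormatError(SpineVBError):
    """File is not a readable 3D volume in a supported format."""


class DimensionalityError(SpineVBError):
    """Image on disk is not three-dimensional."""


class ParameterError(SpineVBError, ValueError):
    """A configuration or call parameter violates its contract."""


class MissingLabelError(SpineVBError, KeyError):
    """Requested label value absent from a label volume."""


class BoundsError(SpineVBError, IndexError):
    """A voxel box or patch extends outside the volume."""


class SamplingError(SpineVBError):
    """No valid patch centers available in the requested region."""


class TrainingError(SpineVBError):
    """Training set is empty or degenerate (e.g. single-class)."""


class InsufficientDataError(SpineVBError):
    """Too few training annotations to estimate a model."""


class DecodingError(SpineVBError):
    """Chain decoding received an empty candidate set."""


class MissingDataError(SpineVBError):
    """No training example carries the requested structure."""


class GridMismatchError(SpineVBError, ValueError):
    """Two maps expected on the same grid have different shapes."""
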