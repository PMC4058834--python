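"""Exception hierarchy.

Every failure mode of the pipeline raises a distinct, named error so that
callers (and the CLI) can report which stage and which contract failed.
"""


class FuzzyMrfError(Exception):
    """Base class for all package errors."""


class MissingFileError(FuzzyMrfError, FileNotFoundError):
    """Input path does not exist."""


class VolumeFormatError(FuzzyMrfError):
    """File exists but is not a readable single-channel image."""


class DimensionalityError(FuzzyMrfError):
    """Image on disk is not three-dimensional."""


class UnwritablePathError(FuzzyMrfError, OSError):
    """Output path cannot be written."""


class GridMismatchError(FuzzyMrfError):
    """Two volumes do not share shape and spacing; message names the attribute."""


class RoiBoundsError(FuzzyMrfError):
    """ROI box is empty, inverted, or extends outside the parent volume."""


class ShapeMismatchError(FuzzyMrfError):
    """Array shape does not match the shape implied by a box or parent grid."""


class ModalityError(FuzzyMrfError):
    """Volume values violate the invariants of the declared modality."""


class ClusteringError(FuzzyMrfError):
    """Fuzzy C-means preconditions violated (too few distinct values, non-finite input, bad k)."""


class DegenerateRegionError(FuzzyMrfError):
    """A rough-segmentation region is too small or has zero variance; message names the parameter."""


class OptimizationError(FuzzyMrfError):
    """Non-finite energy or gradient encountered during descent."""


class ConfigError(FuzzyMrfError):
    """Invalid configuration value (step size, thresholds, spec invariants...)."""
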