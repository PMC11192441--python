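"""Named exceptions raised by latmirror.

Every precondition failure has a distinct class so callers (and the CLI)
can branch on the failure mode rather than parse messages.
"""


class LatmirrorError(Exception):
    """Base class for all latmirror errors."""


# ---------------------------------------------------------------- volumes
class NotThreeDimensionalError(LatmirrorError):
    """Input image is not a 3-D volume."""


class SingularTransformError(LatmirrorError):
    """Voxel-to-world affine is not invertible."""


class ObliqueAxisError(LatmirrorError):
    """No single voxel axis maps onto the world left-right axis."""


class AsymmetricGridError(LatmirrorError):
    """Voxel centres do not pair across the x = 0 plane; mirror operations refuse to run."""


class GridMismatchError(LatmirrorError):
    """Mask and volume are not on the same grid (shape or affine differs)."""


class MidlineNotExcludedError(LatmirrorError):
    """Operation requires a mask that has been through midline exclusion."""


# ----------------------------------------------------------------- mirror
class EmptyHemisphereError(LatmirrorError):
    """Mask contains no left-hemisphere voxels."""


class NoHomologousPairsError(LatmirrorError):
    """No left-hemisphere mask voxel has a homologous right-hemisphere mask voxel."""


class TooFewPairsError(LatmirrorError):
    """Fewer homologous pairs than the subsampling scheme supports."""


class NonFiniteValuesError(LatmirrorError):
    """Difference scores contain NaN or infinity."""


# ---------------------------------------------------------------- toolbox
class ZeroDenominatorError(LatmirrorError):
    """(L - R)/(L + R) undefined because L + R = 0."""


class NoPositiveActivationError(LatmirrorError):
    """No positive statistic values in the ROI; threshold grid undefined."""


class LevelNotRetainedError(LatmirrorError):
    """Bootstrap requested on a threshold level that failed the voxel-count gate."""


class InsufficientActivationError(LatmirrorError):
    """All threshold levels failed the voxel-count gate."""


class DegenerateWeightsError(LatmirrorError):
    """All retained thresholds are zero, so threshold weights sum to zero."""


# ------------------------------------------------------------------- fTCD
class PipelineOrderError(LatmirrorError):
    """Preprocessing stage called out of the fixed pipeline order."""


class NonIntegerFactorError(LatmirrorError):
    """Downsampling factor fs/target_fs is not an integer."""


class NonPositiveMeanError(LatmirrorError):
    """Channel mean is not positive; normalisation undefined."""


class NoCardiacCyclesError(LatmirrorError):
    """No systolic peaks detected; consider overriding the heart-rate band."""


class NoMarkersError(LatmirrorError):
    """Recording carries no trial-onset markers."""


class NoKeptTrialsError(LatmirrorError):
    """Every trial was rejected; nothing to average or fit."""


class RankDeficientDesignError(LatmirrorError):
    """GAM design matrix is rank deficient (e.g. POI spans the whole epoch)."""


# ---------------------------------------------------------------- compare
class ConstantInputError(LatmirrorError):
    """Rank correlation undefined for a constant vector."""


class PairedLengthError(LatmirrorError):
    """Paired inputs differ in length."""
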