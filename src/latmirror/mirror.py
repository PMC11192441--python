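"""Mirror-method laterality index.

The right hemisphere of a t-statistic map is reflected across the
mid-sagittal plane and subtracted from the left hemisphere, giving one
difference score per homologous voxel pair inside the ROI.  The LI is the
mean of those differences, summarised by repeated subsampling: many small
subsets of pairs are drawn, each subset's mean recorded, and the mean and
2.5th/97.5th percentiles of the subset means give the estimate and its 95%
CI.  Small subsets keep spatially adjacent (hence correlated) voxels out of
the same draw.

The method is threshold-free: every value enters regardless of sign, so
asymmetric *deactivation* (both hemispheres negative, one more so)
contributes laterality information that suprathreshold methods discard.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .compare import categorise
from .errors import (
    EmptyHemisphereError,
    MidlineNotExcludedError,
    NoHomologousPairsError,
    NonFiniteValuesError,
    TooFewPairsError,
)
from .results import LiResult
from .volume_io import RoiMask, StatVolume, check_grids_match, lr_axis, mirror_permutation

__all__ = [
    "DifferenceMap",
    "mirror_flip",
    "build_difference_map",
    "mirror_bootstrap",
    "scale_mirror_li",
]


@dataclass(frozen=True)
class DifferenceMap:
    """Per-pair left-minus-right statistic differences inside an ROI.

    ``pair_ids`` are flat voxel indices of the left-hemisphere member of
    each pair, in ascending order, so two runs over the same grid sample
    pairs in the same order.  Voxels on either side whose reflection falls
    outside the mask are dropped and counted, never silently paired.
    """

    pair_ids: np.ndarray
    values: np.ndarray
    n_pairs: int
    n_dropped_left: int
    n_dropped_right: int

    @property
    def n_dropped(self) -> int:
        return self.n_dropped_left + self.n_dropped_right


def mirror_flip(volume: StatVolume) -> StatVolume:
    """Reflect a volume across the mid-sagittal plane x = 0.

    The returned volume holds, at world (x, y, z), the input's value at
    (-x, y, z); shape and affine are unchanged.  An involution: flipping
    twice restores the input bit-exactly.  Refuses asymmetric grids.
    """
    axis, perm = mirror_permutation(volume.affine, volume.shape)
    return StatVolume(np.take(volume.data, perm, axis=axis), volume.affine.copy())


def build_difference_map(volume: StatVolume, mask: RoiMask) -> DifferenceMap:
    """Left-minus-homologous-right differences for every paired mask voxel.

    For each left-hemisphere mask voxel whose reflection is also inside the
    mask, stores ``t_left - t_right``.  Unpaired voxels are dropped and
    counted per side.  No threshold is applied: values of any sign enter.
    """
    check_grids_match(volume, mask)
    if not mask.midline_excluded:
        raise MidlineNotExcludedError(
            "apply exclude_midline() before building a difference map"
        )
    axis, perm = mirror_permutation(volume.affine, volume.shape)
    _, xs = lr_axis(volume.affine, volume.shape)
    view = [1, 1, 1]
    view[axis] = len(xs)
    x = np.broadcast_to(xs.reshape(view), volume.shape)

    mirrored_mask = np.take(mask.data, perm, axis=axis)  # reflection in mask?
    left = mask.data & (x < 0)
    right = mask.data & (x > 0)
    if not left.any():
        raise EmptyHemisphereError("mask has no left-hemisphere voxels")

    paired = left & mirrored_mask
    n_pairs = int(paired.sum())
    if n_pairs == 0:
        raise NoHomologousPairsError(
            "no left-hemisphere mask voxel has a homologous right-hemisphere voxel"
        )
    mirrored_data = np.take(volume.data, perm, axis=axis)
    diffs = (volume.data - mirrored_data)[paired]
    pair_ids = np.flatnonzero(paired.ravel())
    return DifferenceMap(
        pair_ids=pair_ids,
        values=diffs,
        n_pairs=n_pairs,
        n_dropped_left=int(left.sum()) - n_pairs,
        n_dropped_right=int((right & ~mirrored_mask).sum()),
    )


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def mirror_bootstrap(
    diff: DifferenceMap,
    sample_fraction: float = 0.05,
    n_samples: int = 1000,
    seed: int | None = None,
) -> LiResult:
    """Subsample the difference map and summarise the subset means.

    Draws ``n_samples`` independent subsets (without replacement within a
    subset) of ``max(1, round(sample_fraction * n_pairs))`` pairs each.
    The estimate is the mean of the subset means; the CI their 2.5th and
    97.5th percentiles.  Deterministic given ``seed``: subsets are drawn in
    order from a single ``numpy.random.default_rng(seed)`` stream, each as
    one ``choice(n_pairs, size, replace=False)`` call over pair positions
    in ``pair_ids`` order.
    """
    if not (0 < sample_fraction <= 1):
        raise ValueError("sample_fraction must be in (0, 1]")
    if n_samples < 1:
        raise ValueError("n_samples must be positive")
    if diff.n_pairs < 20:
        raise TooFewPairsError(
            f"need at least 20 homologous pairs, got {diff.n_pairs}"
        )
    if not np.all(np.isfinite(diff.values)):
        raise NonFiniteValuesError("difference map contains non-finite values")

    k = max(1, _round_half_up(sample_fraction * diff.n_pairs))
    rng = np.random.default_rng(seed)
    means = np.empty(n_samples)
    for i in range(n_samples):
        idx = rng.choice(diff.n_pairs, size=k, replace=False)
        means[i] = diff.values[idx].mean()
    estimate = float(means.mean())
    ci_low, ci_high = np.percentile(means, [2.5, 97.5])
    return LiResult(
        estimate=estimate,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        method="mirror",
        category=categorise(float(ci_low), float(ci_high)),
        n_units=n_samples,
        seed=seed,
    )


def scale_mirror_li(result: LiResult, divisor: float) -> LiResult:
    """Divide estimate and CI by a positive constant (display scaling).

    A linear transform: laterality category and all rank correlations are
    unchanged.  Used to bring difference scores onto a [-1, 1]-like scale
    by dividing by the sample's absolute maximum difference.
    """
    if divisor <= 0:
        raise ValueError("divisor must be positive")
    return replace(
        result,
        estimate=result.estimate / divisor,
        ci_low=result.ci_low / divisor,
        ci_high=result.ci_high / divisor,
    )
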