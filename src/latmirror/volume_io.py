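"""Statistic volumes, ROI masks, and the left/right convention.

Left and right are defined in *world* space: a voxel is in the left
hemisphere iff its centre has world x < 0.  The convention is derived from
the voxel-to-world affine, never from on-disk storage order, so maps stored
radiologically or neurologically give identical results.

All mirror logic assumes the grid is symmetric about the mid-sagittal plane
x = 0: every voxel centre at world x must have a partner at -x within
0.1 voxel widths.  Grids failing that check refuse to mirror rather than
silently pairing the wrong voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import (
    AsymmetricGridError,
    GridMismatchError,
    MidlineNotExcludedError,
    NotThreeDimensionalError,
    ObliqueAxisError,
    SingularTransformError,
)

__all__ = [
    "StatVolume",
    "RoiMask",
    "read_stat_volume",
    "write_stat_volume",
    "read_roi_mask",
    "write_roi_mask",
    "exclude_midline",
    "hemisphere_values",
    "lr_axis",
    "mirror_permutation",
]

#: relative tolerance (in voxel widths) for pairing centres across x = 0
SYMMETRY_TOL = 0.1


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError("affine must be 4x4")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise SingularTransformError("voxel-to-world affine is singular")
    return affine


@dataclass(frozen=True)
class StatVolume:
    """A 3-D statistic map (unitless t values) with its voxel-to-world affine."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 3:
            raise NotThreeDimensionalError(
                f"expected a 3-D volume, got {data.ndim}-D"
            )
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "affine", _check_affine(self.affine))

    @property
    def shape(self) -> tuple:
        return self.data.shape


@dataclass(frozen=True)
class RoiMask:
    """A binary region-of-interest mask on the same grid as a StatVolume."""

    data: np.ndarray
    affine: np.ndarray
    name: str = "custom"
    midline_excluded: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        data = np.asarray(self.data).astype(bool)
        if data.ndim != 3:
            raise NotThreeDimensionalError(
                f"expected a 3-D mask, got {data.ndim}-D"
            )
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "affine", _check_affine(self.affine))

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


# --------------------------------------------------------------------- I/O
def read_stat_volume(path) -> StatVolume:
    """Read a NIfTI statistic map.

    Raises FileNotFoundError for a missing file, NotThreeDimensionalError
    for a 4-D image and SingularTransformError for a degenerate header
    affine.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise NotThreeDimensionalError(
            f"{path.name} is not a 3-D volume (ndim={data.ndim})"
        )
    return StatVolume(np.asarray(data, dtype=float), img.affine)


def write_stat_volume(volume: StatVolume, path) -> None:
    nib.save(nib.Nifti1Image(volume.data, volume.affine), str(path))


def read_roi_mask(path, name: str = "custom", midline_excluded: bool = False) -> RoiMask:
    """Read a NIfTI mask (nonzero = included)."""
    vol = read_stat_volume(path)
    return RoiMask(vol.data != 0, vol.affine, name=name,
                   midline_excluded=midline_excluded)


def write_roi_mask(mask: RoiMask, path) -> None:
    nib.save(nib.Nifti1Image(mask.data.astype(np.uint8), mask.affine), str(path))


# -------------------------------------------------------- world-x geometry
def lr_axis(affine: np.ndarray, shape) -> tuple[int, np.ndarray]:
    """Identify the voxel axis carrying world x and its centre coordinates.

    Returns ``(axis, xs)`` where ``xs[i]`` is the world x coordinate of
    voxel centres with index ``i`` along ``axis``.  Requires the world x
    row of the affine to involve exactly one voxel axis (no oblique
    left-right axis).
    """
    affine = np.asarray(affine, dtype=float)
    row = affine[0, :3]
    axis = int(np.argmax(np.abs(row)))
    step = row[axis]
    if step == 0:
        raise ObliqueAxisError("world x does not vary along any voxel axis")
    others = np.delete(np.arange(3), axis)
    if np.any(np.abs(row[others]) > 1e-6 * abs(step)):
        raise ObliqueAxisError(
            "world x varies along more than one voxel axis; "
            "resample to an axis-aligned grid first"
        )
    n = shape[axis]
    xs = step * np.arange(n) + affine[0, 3]
    return axis, xs


def mirror_permutation(affine: np.ndarray, shape) -> tuple[int, np.ndarray]:
    """Permutation pairing each x-slab with its reflection across x = 0.

    Returns ``(axis, perm)`` with ``xs[perm[i]] == -xs[i]`` within
    ``SYMMETRY_TOL`` voxel widths.  Raises AsymmetricGridError when any
    centre lacks a partner, since mirroring such a grid would silently
    corrupt the pairing.
    """
    axis, xs = lr_axis(affine, shape)
    step = abs(xs[1] - xs[0]) if len(xs) > 1 else 1.0
    order = np.argsort(xs)
    # reflected coordinates, matched against the sorted centres
    target = -xs
    pos = np.searchsorted(xs[order], target)
    perm = np.empty_like(order)
    tol = SYMMETRY_TOL * step
    for i, t in enumerate(target):
        best = None
        for j in (pos[i] - 1, pos[i], pos[i] + 1):
            if 0 <= j < len(xs):
                cand = order[j]
                if abs(xs[cand] - t) <= tol and (
                    best is None or abs(xs[cand] - t) < abs(xs[best] - t)
                ):
                    best = cand
        if best is None:
            raise AsymmetricGridError(
                f"voxel centre at x={xs[i]:.3f} mm has no partner at "
                f"{-xs[i]:.3f} mm within {tol:.3f} mm"
            )
        perm[i] = best
    return axis, perm


def _world_x_field(affine: np.ndarray, shape) -> np.ndarray:
    """World x per voxel, broadcast to the full grid."""
    axis, xs = lr_axis(affine, shape)
    view = [1, 1, 1]
    view[axis] = len(xs)
    return np.broadcast_to(xs.reshape(view), shape)


def check_grids_match(volume: StatVolume, mask: RoiMask) -> None:
    if volume.shape != mask.shape or not np.allclose(
        volume.affine, mask.affine, atol=1e-6
    ):
        raise GridMismatchError("mask and volume are not on the same grid")


# --------------------------------------------------------------- midline
def exclude_midline(mask: RoiMask, half_width_mm: float = 5.0) -> RoiMask:
    """Remove voxels whose centre lies within ``half_width_mm`` of x = 0.

    The boundary is closed: a centre at exactly |x| = half_width_mm is
    excluded.  Idempotent, and a no-op on masks with no voxels near the
    midline (apart from setting the ``midline_excluded`` flag).
    """
    if half_width_mm < 0:
        raise ValueError("half_width_mm must be non-negative")
    x = _world_x_field(mask.affine, mask.shape)
    keep = np.abs(x) > half_width_mm + 1e-9
    return replace(mask, data=mask.data & keep, midline_excluded=True)


def hemisphere_values(volume: StatVolume, mask: RoiMask) -> tuple[np.ndarray, np.ndarray]:
    """Statistic values at mask voxels, split by hemisphere.

    Left = world x < 0.  Together the two arrays partition the mask.  The
    mask must already be midline-excluded so no voxel sits on the plane
    x = 0 and the split is exhaustive.
    """
    check_grids_match(volume, mask)
    if not mask.midline_excluded:
        raise MidlineNotExcludedError(
            "apply exclude_midline() before splitting hemispheres"
        )
    x = _world_x_field(volume.affine, volume.shape)
    left = mask.data & (x < 0)
    right = mask.data & (x > 0)
    return volume.data[left], volume.data[right]
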