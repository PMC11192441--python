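"""Threshold-bootstrap laterality index.

The classic bounded index LI = (L - R)/(L + R) is computed not at one
activation threshold but across a grid of them: 20 equally spaced t
thresholds from 0 to the ROI maximum.  At each threshold the suprathreshold
values on each side are resampled (100 draws with replacement of 25% of the
side's values), and an LI is formed for every left x right pair of
resamples — 10,000 per threshold.  Thresholds leaving fewer than 10
suprathreshold voxels on either side are discarded.  Per-threshold
distributions are summarised by 25%-trimmed means, combined across
thresholds by a plain, trimmed, or threshold-weighted mean, and the 95% CI
comes from the threshold-weighted pooled histogram of trimmed bootstrap
LIs.

Only positive values ever pass a threshold, so the method is blind to
deactivation: a region that is negative bilaterally contributes nothing,
however asymmetric the deactivation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .compare import categorise
from .errors import (
    DegenerateWeightsError,
    InsufficientActivationError,
    LevelNotRetainedError,
    MidlineNotExcludedError,
    NoPositiveActivationError,
    ZeroDenominatorError,
)
from .results import LiResult
from .volume_io import RoiMask, StatVolume, hemisphere_values

__all__ = [
    "ToolboxConfig",
    "ThresholdLevel",
    "li_formula",
    "make_thresholds",
    "suprathreshold_split",
    "resample_size",
    "bootstrap_threshold",
    "trimmed_mean",
    "combine_levels",
    "weighted_histogram_ci",
    "weighted_percentile",
    "toolbox_li",
]


@dataclass(frozen=True)
class ToolboxConfig:
    """Parameters of the threshold-bootstrap procedure (defaults = the
    method's published defaults: 20 thresholds, 10-voxel gate, 100
    resamples of 25%, 25% trims, threshold-weighted combination)."""

    n_thresholds: int = 20
    min_voxels: int = 10
    n_boot: int = 100
    resample_fraction: float = 0.25
    trim: float = 0.25
    combine: str = "weighted"  # mean | trimmed | weighted
    statistic: str = "sum"     # sum | mean of each resample's values

    def __post_init__(self) -> None:
        if not (0 < self.resample_fraction <= 1):
            raise ValueError("resample_fraction must be in (0, 1]")
        if not (0 <= self.trim < 0.5):
            raise ValueError("trim must be in [0, 0.5)")
        if self.combine not in ("mean", "trimmed", "weighted"):
            raise ValueError(f"unknown combine mode {self.combine!r}")
        if self.statistic not in ("sum", "mean"):
            raise ValueError(f"unknown statistic {self.statistic!r}")
        if self.n_thresholds < 2 or self.n_boot < 1 or self.min_voxels < 1:
            raise ValueError("counts must be positive (n_thresholds >= 2)")


@dataclass(frozen=True)
class ThresholdLevel:
    """One threshold's suprathreshold values and bootstrap LI distribution."""

    threshold: float
    left_values: np.ndarray
    right_values: np.ndarray
    retained: bool
    boot_lis: np.ndarray | None = field(default=None, compare=False)
    trimmed_mean_li: float | None = field(default=None, compare=False)

    @property
    def n_left(self) -> int:
        return len(self.left_values)

    @property
    def n_right(self) -> int:
        return len(self.right_values)


def li_formula(left_total: float, right_total: float) -> float:
    """The conventional laterality index (L - R) / (L + R).

    Bounded in [-1, 1] only when both totals are positive; with negative
    inputs (task deactivation) the ratio is unbounded — e.g. L = 2,
    R = -1 gives 3 — which is why deactivation breaks the conventional LI.
    """
    denom = left_total + right_total
    if denom == 0:
        raise ZeroDenominatorError("L + R = 0; LI undefined")
    return (left_total - right_total) / denom


def make_thresholds(values_in_mask: Sequence[float], n_thresholds: int = 20) -> np.ndarray:
    """Equally spaced thresholds from 0 to the ROI maximum, inclusive."""
    values = np.asarray(values_in_mask, dtype=float)
    if values.size == 0 or np.nanmax(values) <= 0:
        raise NoPositiveActivationError(
            "no positive activation in ROI; threshold grid undefined"
        )
    return np.linspace(0.0, float(np.nanmax(values)), n_thresholds)


def suprathreshold_split(
    volume: StatVolume,
    mask: RoiMask,
    threshold: float,
    min_voxels: int = 10,
) -> ThresholdLevel:
    """Values strictly above ``threshold`` per hemisphere, with the gate.

    ``retained`` is True only when both sides keep at least ``min_voxels``
    suprathreshold voxels; a failed gate is a state, not an error.
    """
    left, right = hemisphere_values(volume, mask)
    lv = left[left > threshold]
    rv = right[right > threshold]
    return ThresholdLevel(
        threshold=float(threshold),
        left_values=lv,
        right_values=rv,
        retained=(len(lv) >= min_voxels and len(rv) >= min_voxels),
    )


def resample_size(n_available: int, fraction: float) -> int:
    """Per-resample draw count: round(fraction * n), at least 1.

    Rounding is half-up so e.g. 25% of 40 voxels -> 10 and of 24 -> 6.
    """
    if n_available < 1:
        raise ValueError("n_available must be at least 1")
    return max(1, int(np.floor(fraction * n_available + 0.5)))


def bootstrap_threshold(
    level: ThresholdLevel,
    config: ToolboxConfig,
    seed: int | None = None,
) -> ThresholdLevel:
    """All left x right resample LIs at one threshold.

    Per side, ``n_boot`` resamples with replacement of
    ``resample_size(n_side, resample_fraction)`` values are drawn (left
    stream first, then right, from one ``default_rng(seed)``), each reduced
    to its sum (or mean, per config).  An LI is computed for every pairing
    of a left with a right resample — ``n_boot ** 2`` values — and the
    trim-trimmed mean of those is stored.
    """
    if not level.retained:
        raise LevelNotRetainedError(
            f"threshold {level.threshold:g} failed the voxel-count gate"
        )
    rng = np.random.default_rng(seed)
    reduce = np.sum if config.statistic == "sum" else np.mean
    k_left = resample_size(level.n_left, config.resample_fraction)
    k_right = resample_size(level.n_right, config.resample_fraction)
    left_tot = reduce(
        rng.choice(level.left_values, size=(config.n_boot, k_left), replace=True),
        axis=1,
    )
    right_tot = reduce(
        rng.choice(level.right_values, size=(config.n_boot, k_right), replace=True),
        axis=1,
    )
    lis = (left_tot[:, None] - right_tot[None, :]) / (
        left_tot[:, None] + right_tot[None, :]
    )
    lis = lis.ravel()
    return replace(
        level,
        boot_lis=lis,
        trimmed_mean_li=trimmed_mean(lis, config.trim),
    )


def trimmed_mean(values: Sequence[float], trim: float) -> float:
    """Mean after dropping floor(trim * n) values from each end (sorted)."""
    values = np.sort(np.asarray(values, dtype=float))
    n = len(values)
    if n == 0:
        raise ValueError("trimmed_mean of empty list")
    if not (0 <= trim < 0.5):
        raise ValueError("trim must be in [0, 0.5)")
    g = int(np.floor(trim * n))
    return float(values[g : n - g].mean())


def _trim_slice(values: np.ndarray, trim: float) -> np.ndarray:
    values = np.sort(values)
    g = int(np.floor(trim * len(values)))
    return values[g : len(values) - g]


def weighted_percentile(values: np.ndarray, weights: np.ndarray, q: float) -> float:
    """Inverse of the right-continuous weighted ECDF (weights normalised).

    Returns the smallest value v with ECDF(v) >= q/100.
    """
    order = np.argsort(values)
    v = values[order]
    w = weights[order].astype(float)
    total = w.sum()
    if total <= 0:
        raise DegenerateWeightsError("weights sum to zero")
    cum = np.cumsum(w)
    i = int(np.searchsorted(cum, q / 100.0 * total, side="left"))
    return float(v[min(i, len(v) - 1)])


def weighted_histogram_ci(
    levels: Sequence[ThresholdLevel],
    trim: float = 0.25,
) -> tuple[float, float]:
    """95% CI from the threshold-weighted pooled bootstrap-LI histogram.

    Pools the trim-retained (middle 1 - 2*trim) bootstrap LIs of every
    retained level, weighting each LI by its level's threshold, and takes
    the 2.5th/97.5th weighted percentiles.  Because each retained level
    contributes the same number of trimmed LIs, the weighted mean of this
    pooled distribution equals the threshold-weighted mean of the
    per-level trimmed means exactly (up to float round-off).
    """
    retained = [l for l in levels if l.retained and l.boot_lis is not None]
    if not retained:
        raise InsufficientActivationError("no retained, bootstrapped levels")
    if all(l.threshold == 0 for l in retained):
        raise DegenerateWeightsError(
            "only the zero threshold was retained; weights are all zero"
        )
    pooled = []
    weights = []
    for l in retained:
        core = _trim_slice(np.asarray(l.boot_lis), trim)
        pooled.append(core)
        weights.append(np.full(len(core), l.threshold))
    pooled = np.concatenate(pooled)
    weights = np.concatenate(weights)
    return (
        weighted_percentile(pooled, weights, 2.5),
        weighted_percentile(pooled, weights, 97.5),
    )


def combine_levels(
    levels: Sequence[ThresholdLevel],
    config: ToolboxConfig,
    seed: int | None = None,
) -> LiResult:
    """Combine per-threshold trimmed-mean LIs into one estimate + CI.

    ``mean``: plain mean of the retained trimmed means.  ``trimmed``:
    trim-trimmed mean of them.  ``weighted``: mean weighted by threshold,
    so higher (more task-specific) thresholds dominate and threshold 0
    contributes nothing.  The CI is always the weighted-histogram CI.
    """
    retained = [l for l in levels if l.retained]
    if not retained:
        detail = "; ".join(
            f"t={l.threshold:g}: L={l.n_left}, R={l.n_right}" for l in levels
        )
        raise InsufficientActivationError(
            f"no threshold retained at least {config.min_voxels} voxels per side "
            f"({detail})"
        )
    if any(l.trimmed_mean_li is None for l in retained):
        raise LevelNotRetainedError("retained levels must be bootstrapped first")
    tms = np.array([l.trimmed_mean_li for l in retained])
    thr = np.array([l.threshold for l in retained])
    if config.combine == "mean":
        estimate = float(tms.mean())
    elif config.combine == "trimmed":
        estimate = trimmed_mean(tms, config.trim)
    else:  # weighted
        if thr.sum() == 0:
            raise DegenerateWeightsError(
                "only the zero threshold was retained; weighted mean undefined"
            )
        estimate = float(np.sum(thr * tms) / thr.sum())
    ci_low, ci_high = weighted_histogram_ci(retained, trim=config.trim)
    return LiResult(
        estimate=estimate,
        ci_low=ci_low,
        ci_high=ci_high,
        method="toolbox",
        category=categorise(ci_low, ci_high),
        n_units=len(retained),
        seed=seed,
    )


def toolbox_li(
    volume: StatVolume,
    mask: RoiMask,
    config: ToolboxConfig | None = None,
    seed: int | None = None,
    return_levels: bool = False,
):
    """Full threshold-bootstrap pipeline for one map and ROI.

    Thresholds are derived from the ROI's pooled (both-hemisphere) values.
    Each threshold level draws from an independent child of
    ``SeedSequence(seed)`` (one child per grid position, whether or not the
    level is retained), so results do not depend on which levels pass the
    gate.  Returns a LiResult with ``n_units`` = number of retained
    thresholds; with ``return_levels=True`` also returns the per-threshold
    table.
    """
    config = config or ToolboxConfig()
    if not mask.midline_excluded:
        raise MidlineNotExcludedError("apply exclude_midline() before toolbox_li")
    left, right = hemisphere_values(volume, mask)
    thresholds = make_thresholds(np.concatenate([left, right]), config.n_thresholds)
    children = np.random.SeedSequence(seed).spawn(len(thresholds))
    levels = []
    for t, child in zip(thresholds, children):
        level = suprathreshold_split(volume, mask, t, config.min_voxels)
        if level.retained:
            level = bootstrap_threshold(
                level, config, seed=np.random.default_rng(child)
            )
        levels.append(level)
    result = combine_levels(levels, config, seed=seed)
    if return_levels:
        return result, levels
    return result
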