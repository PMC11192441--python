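"""Bilateral cerebral blood-flow-velocity (fTCD) pipeline and GAM LI.

Functional transcranial Doppler compares blood-flow velocity in the left
and right middle cerebral arteries during a task.  The pipeline applied
here, in fixed order:

1.  downsample (100 Hz -> 25 Hz by decimation),
2.  sample-level artefact flagging (outside the 0.0001-0.9999 per-channel
    quantiles, plus any user-supplied manual exclusions),
3.  per-channel normalisation to percent of the channel mean,
4.  heart-cycle integration (each cardiac cycle replaced by its mean,
    removing pulsatility),
5.  epoching from -12 s to +30 s around each trial-onset marker,
6.  baseline correction (subtract the mean of the 10 s of rest before
    each trial onset, per trial and side),
7.  trial rejection (any sample outside configurable percent-of-mean
    bounds, judged on the pre-baseline-correction normalised signal),
8.  averaging of kept trials / model fitting.

The LI is the side x period-of-interest (POI) interaction of an additive
model fitted to the long-format kept epochs: a B-spline smooth of time in
epoch absorbs the shared response shape, epoch dummies absorb trial-level
offsets, and the interaction coefficient is the percentage blood-flow
difference between left and right specific to the POI.  Positive = left
dominant.

Each stage refuses to run after a stage that must follow it (out-of-order
calls raise PipelineOrderError), but stages may be unit-tested in
isolation on fresh recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import signal as sps

from .compare import categorise
from .errors import (
    NoCardiacCyclesError,
    NoKeptTrialsError,
    NoMarkersError,
    NonIntegerFactorError,
    NonPositiveMeanError,
    PipelineOrderError,
    RankDeficientDesignError,
)

__all__ = [
    "CbfvRecording",
    "EpochSet",
    "PoiWindow",
    "GamLiFit",
    "STAGE_ORDER",
    "downsample",
    "reject_extreme_samples",
    "normalise",
    "heart_cycle_integrate",
    "epochize",
    "baseline_correct",
    "reject_trials",
    "participant_exclusion",
    "average_epochs",
    "gam_li",
    "scale_ftcd_li",
    "preprocess",
    "subtraction_li",
]

#: fixed stage order; each op refuses to run after any later stage
STAGE_ORDER = (
    "downsample",
    "reject_extreme_samples",
    "normalise",
    "heart_cycle_integrate",
)

#: conventional POI windows (s after trial onset) per task family
DEFAULT_POI = {"generation": (7.0, 17.0), "matching": (7.0, 27.0)}


@dataclass(frozen=True)
class CbfvRecording:
    """Two-channel blood-flow-velocity time series with trial markers.

    ``left`` and ``right`` are velocity samples (arbitrary units before
    normalisation, percent of channel mean after); ``markers`` are sample
    indices of trial onsets (the "clear mind" cue = peri-stimulus time 0).
    ``artefact`` flags samples excluded from mean computation; ``stages``
    logs which pipeline stages have run.
    """

    left: np.ndarray
    right: np.ndarray
    fs: float
    markers: np.ndarray
    artefact: Optional[np.ndarray] = None
    channel_means: Optional[tuple[float, float]] = None
    stages: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        left = np.asarray(self.left, dtype=float)
        right = np.asarray(self.right, dtype=float)
        if left.shape != right.shape or left.ndim != 1:
            raise ValueError("left/right must be equal-length 1-D arrays")
        markers = np.asarray(self.markers, dtype=int)
        if markers.size and (
            np.any(np.diff(markers) <= 0)
            or markers[0] < 0
            or markers[-1] >= len(left)
        ):
            raise ValueError("markers must be strictly increasing and in range")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        object.__setattr__(self, "left", left)
        object.__setattr__(self, "right", right)
        object.__setattr__(self, "markers", markers)

    @property
    def n_samples(self) -> int:
        return len(self.left)

    def _advance(self, stage: str, **changes) -> "CbfvRecording":
        if stage in self.stages:
            raise PipelineOrderError(f"stage {stage!r} already applied")
        later = STAGE_ORDER[STAGE_ORDER.index(stage) + 1 :]
        done_later = [s for s in later if s in self.stages]
        if done_later:
            raise PipelineOrderError(
                f"stage {stage!r} must run before {done_later[0]!r}"
            )
        return replace(self, stages=self.stages + (stage,), **changes)


@dataclass(frozen=True)
class PoiWindow:
    """Period of interest, seconds relative to trial onset."""

    start: float
    end: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("POI end must exceed start")


@dataclass
class EpochSet:
    """Per-trial (time x side) epochs plus inclusion flags.

    ``epochs[trial, sample, side]`` with side 0 = left, 1 = right.  ``raw``
    preserves the pre-baseline-correction normalised signal, which is what
    trial rejection inspects.  A rejected trial keeps its data plus a
    reason code in ``reasons``; ``kept`` is the inclusion flag.
    """

    epochs: np.ndarray
    time: np.ndarray
    fs: float
    kept: np.ndarray
    reasons: list
    raw: np.ndarray = field(default=None)  # type: ignore[assignment]
    baseline_corrected: bool = False

    def __post_init__(self) -> None:
        if self.raw is None:
            self.raw = self.epochs.copy()

    @property
    def n_trials(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_rejected(self) -> int:
        return int((~self.kept).sum())


@dataclass(frozen=True)
class GamLiFit:
    """Side x POI interaction LI from the additive model.

    ``li`` is the percentage blood-flow difference (left minus right)
    specific to the POI; ``ci = li +/- 1.96 * se``.
    """

    li: float
    se: float
    ci_low: float
    ci_high: float
    n_trials_used: int
    terms: dict
    category: str

    @property
    def estimate(self) -> float:  # uniform interface with LiResult
        return self.li


# ------------------------------------------------------------ recording ops
def downsample(rec: CbfvRecording, target_fs: float = 25.0) -> CbfvRecording:
    """Decimate both channels to ``target_fs`` by keeping every k-th sample.

    k = fs / target_fs must be an integer.  Marker indices are divided by k
    and floored.
    """
    factor = rec.fs / target_fs
    if abs(factor - round(factor)) > 1e-9 or factor < 1:
        raise NonIntegerFactorError(
            f"fs {rec.fs} is not an integer multiple of target {target_fs}"
        )
    k = int(round(factor))
    return rec._advance(
        "downsample",
        left=rec.left[::k],
        right=rec.right[::k],
        markers=rec.markers // k,
        fs=target_fs,
        artefact=None if rec.artefact is None else rec.artefact[::k],
    )


def reject_extreme_samples(
    rec: CbfvRecording,
    q_low: float = 0.0001,
    q_high: float = 0.9999,
    manual: Sequence[int] = (),
) -> CbfvRecording:
    """Flag samples outside per-channel empirical quantile bands.

    Flagged samples (plus any ``manual`` indices, the stand-in for manual
    gross-artefact rejection) are excluded from channel means and mark any
    epoch that overlaps them.  A constant channel has a zero-width band and
    flags nothing.
    """
    if rec.n_samples == 0:
        raise ValueError("empty recording")
    flags = np.zeros(rec.n_samples, dtype=bool)
    for chan in (rec.left, rec.right):
        lo, hi = np.quantile(chan, [q_low, q_high])
        flags |= (chan < lo) | (chan > hi)
    if len(manual):
        flags[np.asarray(manual, dtype=int)] = True
    return rec._advance("reject_extreme_samples", artefact=flags)


def normalise(rec: CbfvRecording) -> CbfvRecording:
    """Divide each channel by its own mean and express as percent.

    Means are computed over artefact-free samples; after this stage each
    channel's (artefact-free) mean is 100%.
    """
    ok = ~rec.artefact if rec.artefact is not None else np.ones(rec.n_samples, bool)
    means = (float(rec.left[ok].mean()), float(rec.right[ok].mean()))
    if means[0] <= 0 or means[1] <= 0:
        raise NonPositiveMeanError(f"channel means must be positive, got {means}")
    return rec._advance(
        "normalise",
        left=100.0 * rec.left / means[0],
        right=100.0 * rec.right / means[1],
        channel_means=means,
    )


def heart_cycle_integrate(
    rec: CbfvRecording,
    rate_band_bpm: tuple[float, float] = (40.0, 150.0),
) -> CbfvRecording:
    """Replace each cardiac cycle by its per-channel mean.

    Systolic peaks are detected on the summed channels with a minimum
    separation of 60/max-rate seconds and a prominence scaled to the
    signal's interquartile range; samples between consecutive peaks form a
    cycle.  Fully deterministic.  A constant recording passes through
    unchanged (integration of a constant is that constant).
    """
    combined = rec.left + rec.right
    if np.ptp(combined) < 1e-12:
        return rec._advance("heart_cycle_integrate")
    iqr = float(np.subtract(*np.percentile(combined, [75, 25])))
    distance = max(1, int(round(rec.fs * 60.0 / rate_band_bpm[1])))
    peaks, _ = sps.find_peaks(combined, distance=distance, prominence=0.5 * iqr)
    if len(peaks) == 0:
        raise NoCardiacCyclesError(
            "no systolic peaks detected; override rate_band_bpm if the "
            "heart rate is outside 40-150 bpm"
        )
    bounds = np.concatenate([[0], peaks, [rec.n_samples]])
    left = rec.left.copy()
    right = rec.right.copy()
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b > a:
            left[a:b] = rec.left[a:b].mean()
            right[a:b] = rec.right[a:b].mean()
    return rec._advance("heart_cycle_integrate", left=left, right=right)


# --------------------------------------------------------------- epoch ops
def epochize(
    rec: CbfvRecording,
    window: tuple[float, float] = (-12.0, 30.0),
) -> EpochSet:
    """Cut one epoch per marker, spanning ``window`` seconds around onset.

    Trials whose window runs off either end of the recording are flagged
    ``"truncated"`` (data zero-padded), not silently dropped.  Epochs that
    overlap flagged artefact samples are flagged ``"artefact"``.
    """
    if rec.markers.size == 0:
        raise NoMarkersError("recording has no trial-onset markers")
    lo = int(round(window[0] * rec.fs))
    hi = int(round(window[1] * rec.fs))
    n_t = hi - lo
    time = (np.arange(n_t) + lo) / rec.fs
    n_trials = len(rec.markers)
    epochs = np.zeros((n_trials, n_t, 2))
    kept = np.ones(n_trials, dtype=bool)
    reasons: list = [None] * n_trials
    for i, m in enumerate(rec.markers):
        a, b = m + lo, m + hi
        if a < 0 or b > rec.n_samples:
            kept[i] = False
            reasons[i] = "truncated"
            aa, bb = max(a, 0), min(b, rec.n_samples)
            epochs[i, aa - a : aa - a + (bb - aa), 0] = rec.left[aa:bb]
            epochs[i, aa - a : aa - a + (bb - aa), 1] = rec.right[aa:bb]
            continue
        epochs[i, :, 0] = rec.left[a:b]
        epochs[i, :, 1] = rec.right[a:b]
        if rec.artefact is not None and rec.artefact[a:b].any():
            kept[i] = False
            reasons[i] = "artefact"
    return EpochSet(epochs=epochs, time=time, fs=rec.fs, kept=kept, reasons=reasons)


def baseline_correct(
    epochs: EpochSet,
    baseline: tuple[float, float] = (-10.0, 0.0),
) -> EpochSet:
    """Subtract each trial's per-side mean over the baseline window.

    The window is [start, end): the 10 s of rest immediately before trial
    onset by default.  After correction every trial's baseline-window mean
    is zero per side.
    """
    if epochs.baseline_corrected:
        raise PipelineOrderError("epochs already baseline-corrected")
    sel = (epochs.time >= baseline[0]) & (epochs.time < baseline[1])
    if not sel.any():
        raise ValueError("baseline window contains no samples")
    base = epochs.epochs[:, sel, :].mean(axis=1, keepdims=True)
    return EpochSet(
        epochs=epochs.epochs - base,
        time=epochs.time,
        fs=epochs.fs,
        kept=epochs.kept.copy(),
        reasons=list(epochs.reasons),
        raw=epochs.raw,
        baseline_corrected=True,
    )


def reject_trials(
    epochs: EpochSet,
    low_pct: float = 60.0,
    high_pct: float = 140.0,
) -> EpochSet:
    """Flag trials with any normalised sample outside [low_pct, high_pct].

    Judged on the pre-baseline-correction normalised signal (percent of
    channel mean, which is 100 by construction), so the rule is the same
    whether it runs before or after baseline correction.  Reason codes:
    ``"low-signal"`` / ``"high-signal"``.
    """
    kept = epochs.kept.copy()
    reasons = list(epochs.reasons)
    for i in range(epochs.n_trials):
        if not kept[i]:
            continue
        trial = epochs.raw[i]
        if (trial < low_pct).any():
            kept[i] = False
            reasons[i] = "low-signal"
        elif (trial > high_pct).any():
            kept[i] = False
            reasons[i] = "high-signal"
    return EpochSet(
        epochs=epochs.epochs,
        time=epochs.time,
        fs=epochs.fs,
        kept=kept,
        reasons=reasons,
        raw=epochs.raw,
        baseline_corrected=epochs.baseline_corrected,
    )


def participant_exclusion(
    epochs: EpochSet,
    max_reject_fraction: float = 0.20,
) -> tuple[bool, int, int]:
    """Whether a participant exceeds the tolerated trial-rejection rate.

    Returns ``(excluded, n_rejected, allowed)`` where ``allowed`` is
    ``round(max_reject_fraction * n_trials)`` (half-up) and exclusion
    triggers when ``n_rejected > allowed``: 3 of 15 trials is tolerated,
    a 4th triggers exclusion; 5 of 23 is tolerated.
    """
    n = epochs.n_trials
    allowed = int(np.floor(max_reject_fraction * n + 0.5))
    return epochs.n_rejected > allowed, epochs.n_rejected, allowed


def average_epochs(epochs: EpochSet) -> pd.DataFrame:
    """Pointwise mean over kept trials per side, plus the L-R trace.

    Returns a DataFrame with columns ``time``, ``left``, ``right``,
    ``diff`` (left minus right).
    """
    if not epochs.kept.any():
        raise NoKeptTrialsError("all trials rejected; nothing to average")
    mean = epochs.epochs[epochs.kept].mean(axis=0)
    return pd.DataFrame(
        {
            "time": epochs.time,
            "left": mean[:, 0],
            "right": mean[:, 1],
            "diff": mean[:, 0] - mean[:, 1],
        }
    )


# ------------------------------------------------------------------ model
def _bspline_basis(t: np.ndarray, df: int) -> np.ndarray:
    """Cubic B-spline basis with df columns (partition of unity, so it
    spans the constant and replaces an explicit intercept)."""
    from scipy.interpolate import BSpline

    k = 3
    n_interior = df - k - 1
    if n_interior < 0:
        raise ValueError("spline_df must be at least 4 for a cubic basis")
    lo, hi = float(t.min()), float(t.max())
    interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
    knots = np.concatenate([[lo] * (k + 1), interior, [hi] * (k + 1)])
    return BSpline.design_matrix(t, knots, k).toarray()


def gam_li(
    epochs: EpochSet,
    poi: PoiWindow,
    spline_df: int = 10,
) -> GamLiFit:
    """LI as the side x POI interaction of an additive model.

    Long-format kept epochs are fitted by OLS with: a cubic B-spline smooth
    of time in epoch (``spline_df`` columns, absorbing the shared response
    shape and the intercept), a side indicator (1 = left), a POI boxcar
    (``poi.start <= t < poi.end``), per-epoch dummies, and side x POI.
    The interaction coefficient is the percentage blood-flow difference
    between sides specific to the POI; its conventional OLS standard error
    gives ``ci = li +/- 1.96 se``.  Swapping channel labels negates ``li``
    exactly, and in the noise-free piecewise-constant limit ``li`` reduces
    to mean(L - R in POI) - mean(L - R outside POI).
    """
    kept_idx = np.flatnonzero(epochs.kept)
    if len(kept_idx) < 2:
        raise NoKeptTrialsError("need at least 2 kept trials for the model")
    if not (epochs.time.min() <= poi.start and poi.end <= epochs.time.max() + 1.0 / epochs.fs):
        raise ValueError("POI must lie within the epoch span")

    n_t = len(epochs.time)
    basis = _bspline_basis(epochs.time, spline_df)
    poi_box = ((epochs.time >= poi.start) & (epochs.time < poi.end)).astype(float)

    blocks_X = []
    blocks_y = []
    n_ep = len(kept_idx)
    for j, i in enumerate(kept_idx):
        for side, name in ((0, 1.0), (1, 0.0)):  # 1 = left
            side_col = np.full(n_t, name)
            ep_dummies = np.zeros((n_t, n_ep - 1))
            if j > 0:
                ep_dummies[:, j - 1] = 1.0
            X = np.column_stack(
                [basis, side_col, poi_box, side_col * poi_box, ep_dummies]
            )
            blocks_X.append(X)
            blocks_y.append(epochs.epochs[i, :, side])
    X = np.vstack(blocks_X)
    y = np.concatenate(blocks_y)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RankDeficientDesignError(
            "design matrix is rank deficient (is the POI the whole epoch?)"
        )
    fit = sm.OLS(y, X).fit()
    i_int = basis.shape[1] + 2  # column order: basis, side, poi, side*poi
    li = float(fit.params[i_int])
    se = float(fit.bse[i_int])
    ci_low, ci_high = li - 1.96 * se, li + 1.96 * se
    return GamLiFit(
        li=li,
        se=se,
        ci_low=ci_low,
        ci_high=ci_high,
        n_trials_used=n_ep,
        terms={
            "smooth_df": basis.shape[1],
            "epoch_levels": n_ep,
            "poi": (poi.start, poi.end),
            "residual_df": int(fit.df_resid),
        },
        category=categorise(ci_low, ci_high),
    )


def scale_ftcd_li(fit: GamLiFit, divisor: float = 6.0) -> GamLiFit:
    """Divide the LI, its SE and CI by a positive constant (display
    scaling onto the same axis as the fMRI indices); ranks and the
    laterality category are unchanged."""
    if divisor <= 0:
        raise ValueError("divisor must be positive")
    return replace(
        fit,
        li=fit.li / divisor,
        se=fit.se / divisor,
        ci_low=fit.ci_low / divisor,
        ci_high=fit.ci_high / divisor,
    )


def subtraction_li(epochs: EpochSet, poi: PoiWindow) -> float:
    """Reference plain-subtraction LI: mean(L - R in POI) - mean(L - R
    outside POI) over kept trials.  Kept as the closed-form limit the GAM
    interaction must match on noise-free piecewise-constant epochs."""
    avg = average_epochs(epochs)
    in_poi = (avg["time"] >= poi.start) & (avg["time"] < poi.end)
    return float(avg.loc[in_poi, "diff"].mean() - avg.loc[~in_poi, "diff"].mean())


# -------------------------------------------------------------- pipeline
def preprocess(
    rec: CbfvRecording,
    target_fs: float = 25.0,
    window: tuple[float, float] = (-12.0, 30.0),
    baseline: tuple[float, float] = (-10.0, 0.0),
    bounds: tuple[float, float] = (60.0, 140.0),
    manual: Sequence[int] = (),
) -> EpochSet:
    """Run the full fixed-order preprocessing chain on a raw recording."""
    if rec.fs != target_fs:
        rec = downsample(rec, target_fs)
    rec = reject_extreme_samples(rec, manual=manual)
    rec = normalise(rec)
    rec = heart_cycle_integrate(rec)
    epochs = epochize(rec, window=window)
    epochs = baseline_correct(epochs, baseline=baseline)
    epochs = reject_trials(epochs, low_pct=bounds[0], high_pct=bounds[1])
    return epochs
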