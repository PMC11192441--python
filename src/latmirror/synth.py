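"""Synthetic statistic maps and Doppler recordings with known ground truth.

Two generators cover the package's input modalities:

* ``generate_tmap`` places mirrored spherical activation (or deactivation)
  blobs of independent left/right amplitude on a left-right-symmetric
  grid, optionally smooths, and adds Gaussian noise.  The truth record
  carries each blob's amplitude gap, so the expected sign of every
  laterality estimate is known by construction.

* ``generate_cbfv`` builds a pulsatile two-channel velocity recording with
  a task-locked bilateral response, a lateralised offset added to the left
  channel inside the period of interest, optional artefact spikes, and
  trial-onset markers.

Both are pure functions of (spec, seed).  ``generate_epoch_set`` is a
shortcut that emits ready-made normalised epochs for exercising the GAM
estimator without the signal-level pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .ftcd import CbfvRecording, EpochSet
from .volume_io import RoiMask, StatVolume

__all__ = [
    "Blob",
    "TmapSpec",
    "CbfvSpec",
    "generate_tmap",
    "generate_cbfv",
    "generate_epoch_set",
    "generate_study_cohort",
]


@dataclass(frozen=True)
class Blob:
    """A mirrored pair of spheres: centre (|x| is reflected to both
    hemispheres), radius in mm, and independent left/right amplitudes.
    Negative amplitudes model task-related deactivation."""

    centre_mm: tuple[float, float, float]
    radius_mm: float
    amp_left: float
    amp_right: float

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("radius must be positive")


@dataclass(frozen=True)
class TmapSpec:
    """Synthetic t-map specification on a symmetric grid.

    Default grid: 32^3 voxels of 2 mm, centred so voxel centres sit at odd
    millimetre offsets, symmetric about x = 0 (a desk-scale stand-in for a
    standard 2 mm template grid).  Smoothing (FWHM mm) is applied after
    blob placement and before noise.
    """

    blobs: tuple = ()
    shape: tuple[int, int, int] = (32, 32, 32)
    voxel_mm: float = 2.0
    noise_sd: float = 0.0
    smooth_fwhm_mm: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.smooth_fwhm_mm < 0:
            raise ValueError("noise_sd and smooth_fwhm_mm must be non-negative")


@dataclass(frozen=True)
class CbfvSpec:
    """Synthetic bilateral CBFV recording specification.

    Trial structure follows the task design it emulates: a 5 s cue, 20 s
    of task, 25 s of rest (50 s per trial), 23 trials, sampled at 100 Hz.
    ``delta_pct`` is the lateralised ground truth: a percentage of the
    left channel's baseline added inside the POI of every trial.  The
    pulsatile base is a raised-cosine train at ``heart_rate_bpm``.
    """

    n_trials: int = 23
    cue_s: float = 5.0
    task_s: float = 20.0
    rest_s: float = 25.0
    fs: float = 100.0
    heart_rate_bpm: float = 70.0
    base_left: float = 60.0
    base_right: float = 54.0
    pulse_depth: float = 0.2
    response_amp_pct: float = 8.0
    delta_pct: float = 0.0
    poi: tuple[float, float] = (7.0, 17.0)
    noise_sd_pct: float = 1.0
    spikes: tuple = ()  # (time_s, magnitude_pct) pairs
    pre_s: float = 15.0
    post_s: float = 35.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("need at least one trial")
        if self.trial_s <= 0:
            raise ValueError("trial structure must have positive duration")
        if not np.isfinite(self.delta_pct):
            raise ValueError("delta_pct must be finite")

    @property
    def trial_s(self) -> float:
        return self.cue_s + self.task_s + self.rest_s


# ----------------------------------------------------------------- t-maps
def _symmetric_affine(shape, voxel_mm: float) -> np.ndarray:
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    affine[:3, 3] = -voxel_mm * (np.asarray(shape) - 1) / 2.0
    return affine


def generate_tmap(spec: TmapSpec):
    """Build a synthetic statistic volume plus one bilateral ROI per blob.

    Returns ``(volume, masks, truth)`` where ``masks`` is a list of
    RoiMask (the union of a blob's two spheres, before midline exclusion)
    and ``truth`` records per blob the left/right amplitudes, their gap
    (``amp_left - amp_right``, whose sign is the expected laterality) and
    the generator seed.
    """
    affine = _symmetric_affine(spec.shape, spec.voxel_mm)
    ii = np.indices(spec.shape).reshape(3, -1)
    world = (affine[:3, :3] @ ii + affine[:3, 3:]).T.reshape(*spec.shape, 3)

    data = np.zeros(spec.shape)
    masks = []
    truth = {"seed": spec.seed, "blobs": []}
    half_extent = np.abs(world).max(axis=(0, 1, 2))
    for blob in spec.blobs:
        cx, cy, cz = blob.centre_mm
        left_c = np.array([-abs(cx), cy, cz])
        right_c = np.array([abs(cx), cy, cz])
        for c in (left_c, right_c):
            if np.any(np.abs(c) + blob.radius_mm > half_extent + spec.voxel_mm):
                raise ValueError(f"blob at {tuple(c)} extends outside the grid")
        left_sph = np.linalg.norm(world - left_c, axis=-1) <= blob.radius_mm
        right_sph = np.linalg.norm(world - right_c, axis=-1) <= blob.radius_mm
        data += blob.amp_left * left_sph + blob.amp_right * right_sph
        masks.append(RoiMask(left_sph | right_sph, affine))
        truth["blobs"].append(
            {
                "amp_left": blob.amp_left,
                "amp_right": blob.amp_right,
                "gap": blob.amp_left - blob.amp_right,
                "expected_sign": int(np.sign(blob.amp_left - blob.amp_right)),
            }
        )
    if spec.smooth_fwhm_mm > 0:
        sigma = spec.smooth_fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / spec.voxel_mm
        data = ndimage.gaussian_filter(data, sigma)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        data = data + rng.normal(0.0, spec.noise_sd, size=spec.shape)
    return StatVolume(data, affine), masks, truth


# ------------------------------------------------------------- recordings
def generate_cbfv(spec: CbfvSpec):
    """Build a synthetic bilateral CBFV recording.

    Each channel is ``base * (1 + pulse_depth * cos(2 pi f_heart t)
    + (response(t) + delta(t) + noise)/100)`` where ``response`` is a
    smooth task-locked bump shared by both sides and ``delta`` adds
    ``delta_pct`` to the *left* channel inside each trial's POI.  Returns
    ``(recording, truth)``; truth holds delta, the POI and spike sample
    indices.
    """
    total_s = spec.pre_s + spec.n_trials * spec.trial_s + spec.post_s
    n = int(round(total_s * spec.fs))
    t = np.arange(n) / spec.fs
    rng = np.random.default_rng(spec.seed)

    onsets_s = spec.pre_s + np.arange(spec.n_trials) * spec.trial_s
    markers = np.round(onsets_s * spec.fs).astype(int)

    # task-locked components, expressed in percent of channel baseline
    response = np.zeros(n)
    delta = np.zeros(n)
    for on in onsets_s:
        tt = t - on
        in_resp = (tt >= 2.0) & (tt <= spec.cue_s + spec.task_s + 3.0)
        span = spec.cue_s + spec.task_s + 1.0
        response[in_resp] += spec.response_amp_pct * np.sin(
            np.pi * (tt[in_resp] - 2.0) / span
        ) ** 2
        delta[(tt >= spec.poi[0]) & (tt < spec.poi[1])] += spec.delta_pct

    pulse = spec.pulse_depth * np.cos(2.0 * np.pi * spec.heart_rate_bpm / 60.0 * t)
    spike_samples = []
    spike_pct = np.zeros(n)
    for time_s, mag_pct in spec.spikes:
        idx = int(round(time_s * spec.fs))
        if 0 <= idx < n:
            spike_pct[idx] += mag_pct
            spike_samples.append(idx)

    def channel(base: float, lateral: np.ndarray) -> np.ndarray:
        noise = rng.normal(0.0, spec.noise_sd_pct, size=n) if spec.noise_sd_pct > 0 else 0.0
        return base * (1.0 + pulse + (response + lateral + spike_pct + noise) / 100.0)

    left = channel(spec.base_left, delta)
    right = channel(spec.base_right, np.zeros(n))
    rec = CbfvRecording(left=left, right=right, fs=spec.fs, markers=markers)
    truth = {
        "delta_pct": spec.delta_pct,
        "poi": list(spec.poi),
        "spike_samples": spike_samples,
        "seed": spec.seed,
    }
    return rec, truth


def generate_epoch_set(
    n_trials: int = 8,
    delta_pct: float = 0.0,
    noise_sd_pct: float = 1.0,
    fs: float = 25.0,
    window: tuple[float, float] = (-12.0, 30.0),
    poi: tuple[float, float] = (7.0, 17.0),
    response_amp_pct: float = 8.0,
    trial_scatter_pct: float = 0.5,
    seed: int = 0,
) -> EpochSet:
    """Ready-made normalised, baseline-corrected epochs for the GAM.

    Each trial is a shared smooth response bump plus ``delta_pct`` on the
    left channel inside the POI, a per-trial offset (SD
    ``trial_scatter_pct``, absorbed by the model's epoch terms) and iid
    Gaussian noise.  Under these conditions the model's assumptions hold
    exactly, so its CI calibration can be checked directly.
    """
    rng = np.random.default_rng(seed)
    n_t = int(round((window[1] - window[0]) * fs))
    time = np.arange(n_t) / fs + window[0]
    resp = np.zeros(n_t)
    in_resp = (time >= 2.0) & (time <= 28.0)
    resp[in_resp] = response_amp_pct * np.sin(np.pi * (time[in_resp] - 2.0) / 26.0) ** 2
    poi_box = (time >= poi[0]) & (time < poi[1])

    epochs = np.empty((n_trials, n_t, 2))
    for i in range(n_trials):
        offset = rng.normal(0.0, trial_scatter_pct)
        for side in (0, 1):
            lateral = delta_pct * poi_box if side == 0 else 0.0
            noise = rng.normal(0.0, noise_sd_pct, size=n_t)
            epochs[i, :, side] = resp + lateral + offset + noise
    return EpochSet(
        epochs=epochs,
        time=time,
        fs=fs,
        kept=np.ones(n_trials, dtype=bool),
        reasons=[None] * n_trials,
        baseline_corrected=True,
    )


def generate_study_cohort(n_subjects: int = 30, seed: int = 0, noise_sd: float = 1.0):
    """A weakly lateralised synthetic cohort of statistic maps.

    Each subject's map combines the three features that task maps show in
    practice and that drive the two fMRI estimators apart:

    * a strong, symmetric focal activation peak (amplitude 8) that
      dominates the high activation thresholds but carries no laterality,
    * a broad, weakly lateralised activation region (amplitude 2.5, with a
      per-subject left-right gap drawn from N(0.5, 0.25)),
    * a bilaterally *deactivated* region whose deactivation is more marked
      on the right (gap also N(0.5, 0.25)) — laterality information that
      suprathreshold methods cannot see.

    With voxel noise SD 1.0 the gaps are small relative to noise, so
    lateralisation is weak.  Because the suprathreshold LI then changes
    with threshold (lateralised at low thresholds, symmetric at high
    ones), the threshold-bootstrap CI is wide, while the mirror method
    pools the activation and deactivation asymmetries into a narrow
    difference-score CI.

    Yields ``(volume, roi_mask, truth)`` per subject; the ROI is the
    midline-excluded union of the three regions, and ``truth`` carries the
    drawn gaps.  Deterministic given ``seed``.
    """
    from .volume_io import exclude_midline

    rng = np.random.default_rng(seed)
    for s in range(n_subjects):
        gap_act = rng.normal(0.5, 0.25)
        gap_deact = rng.normal(0.5, 0.25)
        spec = TmapSpec(
            blobs=(
                Blob((16, 10, 10), 6.0, 8.0, 8.0),
                Blob((14, -10, -6), 11.0, 2.5 + gap_act / 2, 2.5 - gap_act / 2),
                Blob((12, 12, -12), 9.0, -1.5, -1.5 - gap_deact),
            ),
            noise_sd=noise_sd,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        volume, masks, _ = generate_tmap(spec)
        union = RoiMask(
            masks[0].data | masks[1].data | masks[2].data, masks[0].affine,
            name="mca",
        )
        truth = {"gap_act": gap_act, "gap_deact": gap_deact, "subject": s}
        yield volume, exclude_midline(union), truth
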