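# Methods

This note records the models and procedures latmirror implements, the
defaults and why, the numerical conventions that make results
bit-reproducible, and what the synthetic generators do and do not emulate.

## Conventions shared by the fMRI estimators

**Left/right is a world-space notion.** A voxel belongs to the left
hemisphere iff its centre has world x < 0, derived from the NIfTI affine
— never from on-disk storage order, which varies between radiological and
neurological conventions. The affine's world-x row must involve exactly
one voxel axis; oblique left-right axes are refused rather than
approximated.

**Grid symmetry is checked, not assumed.** Mirror operations require
every voxel centre at world x to have a partner at −x within 0.1 voxel
widths; otherwise they raise. A silent nearest-neighbour pairing on an
asymmetric grid would corrupt the difference scores without any visible
symptom.

**Midline exclusion** removes voxels whose centre lies within 5 mm of
x = 0 (both hemispheres' medial surfaces blur together there, and the
x = 0 ≙ longitudinal-fissure assumption is weakest at the midline). The
band is closed: a centre at exactly |x| = 5 mm is excluded. The boundary
choice is a convention of this package; nothing downstream is sensitive
to it beyond the single voxel layer it moves.

## Mirror method

For each left-hemisphere ROI voxel whose reflection also lies in the ROI,
the difference d = t_left − t_right is recorded; unpaired voxels on
either side are dropped and counted. No threshold is applied.

The summary draws `n_samples = 1000` independent subsets (without
replacement within a subset) of `max(1, round(0.05 · n_pairs))` pairs;
the estimate is the mean of subset means and the CI their 2.5th/97.5th
percentiles. The 5% default follows from pilot evidence that small
subsets minimise correlations between spatially adjacent voxels in a
sample; the fraction is exposed as configuration and the package does not
re-derive that pilot result. Subsets are drawn independently rather than
as a mutually exclusive partition (a partition would cap the number of
subsets at 20).

RNG contract: one `numpy.random.default_rng(seed)` stream, one
`choice(n_pairs, k, replace=False)` call per subset in order, with pairs
indexed in ascending flat-voxel order. This makes runs bit-reproducible
and gives exact antisymmetry: mirroring the input volume negates every
difference score while preserving pair order, so the same seed yields the
exactly negated estimate.

Half-up rounding (`floor(x + 0.5)`) is used for subset sizes here and for
resample sizes in the threshold-bootstrap method, avoiding Python's
round-half-to-even surprises.

`scale_mirror_li` divides estimate and CI by a user-supplied constant
(conventionally the cohort's absolute maximum difference) for display on
a [−1, 1]-like axis; being linear, it changes neither ranks nor
categories. Scaled mirror LIs are difference scores, not proportions.

## Threshold-bootstrap method

Thresholds: `linspace(0, max t in ROI, 20)` — endpoints inclusive, so
spacing is max/19. The comparison is strictly greater-than, which at
threshold 0 drops exact zeros (consistent with "above threshold") and
guarantees every suprathreshold sum is positive, so no LI denominator can
vanish at any threshold.

Per retained threshold (≥ 10 suprathreshold voxels on *each* side), each
side draws 100 resamples with replacement of `round(0.25 · n_side)`
values (minimum 1); each resample is reduced to its **sum** (a `mean`
switch is provided, since resample sizes already encode the sides'
voxel-count shares and the literature is not explicit on this point), and
an LI is computed for all 100 × 100 pairings. Draw order is left stream
then right from one seeded generator; each threshold level consumes an
independent child of `SeedSequence(seed)` (one child per grid position,
whether or not the level is retained), so results do not depend on which
levels pass the gate.

Trimming is by count — drop `floor(0.25 · n)` from each end after
sorting — deterministic for any n.

Combination: `weighted` (default) is Σ tᵢ·LIᵢ / Σ tᵢ over retained
levels, so threshold 0 receives weight zero by construction; `mean` and
`trimmed` are provided. The CI pools each retained level's middle-50%
bootstrap LIs, weights every pooled value by its level's threshold, and
takes the 2.5th/97.5th percentiles of the inverse right-continuous
weighted ECDF (weights normalised). Because every retained level
contributes the same number of trimmed values, the weighted mean of this
pooled distribution equals the threshold-weighted combination identically
(asserted to 1e-10 in the tests).

Degenerate cases: an ROI with no positive values has no threshold grid
and raises; a run in which only the zero threshold survives the gate has
all-zero weights and raises rather than returning an arbitrary number.

## fTCD pipeline and GAM

Stage order is fixed: downsample (decimation, 100 → 25 Hz; marker indices
floored) → sample-level artefact flags (outside the per-channel
0.0001–0.9999 quantiles, plus a user-supplied manual exclusion list) →
normalisation (each channel to percent of its own artefact-free mean) →
heart-cycle integration → epoching (−12 to 30 s; truncated trials flagged,
not dropped; epochs overlapping flagged samples marked "artefact") →
baseline correction (per trial and side, subtract the mean over
[−10, 0) s) → trial rejection → averaging / model fitting. Each recording
operation refuses to run after a stage that must follow it; running a
stage in isolation on a fresh recording is allowed so stages remain unit
testable.

Heart-cycle integration detects systolic peaks on the summed channels
(`scipy.signal.find_peaks`, minimum separation 60/150 s ≙ a 150 bpm
ceiling, prominence 0.5 × the signal's interquartile range) and replaces
each between-peak segment by its per-channel mean. It is deterministic
and amplitude-scale-free; a constant recording passes through unchanged.
If no peaks are found the error suggests overriding the rate band.

Trial rejection flags trials containing any *pre-baseline-correction*
normalised sample below 60% or above 140% of the channel mean. The upper
default is an implementation choice: an upper bound of 100% — the mean
itself — would reject every trial of a signal normalised to mean 100, so
the package defaults to a symmetric-in-spirit 140% while leaving both
bounds configurable.

Participant-level exclusion triggers when more than `round(0.20 ·
n_trials)` trials are rejected (half-up): 3 of 15 trials are tolerated,
as are 5 of 23.

The LI model is fitted by OLS on the long-format kept epochs: a cubic
B-spline basis over epoch time (`spline_df = 10` columns; a partition of
unity, so it absorbs the intercept and the shared response shape), a side
indicator (1 = left), a POI boxcar (`start ≤ t < end`), per-epoch dummies
(first level dropped), and the side × POI interaction, whose coefficient
is the LI: the percentage blood-flow difference between sides specific to
the POI. With this coding the estimator has two exact properties: swapping
the channel labels negates the LI with identical SE, and on noise-free
epochs that are constant inside/outside the POI it reduces to the plain
subtraction LI, mean(L−R in POI) − mean(L−R outside). The CI is li ±
1.96·se with conventional OLS standard errors. POI windows are task
parameters, not universal constants; the package documents 7–17 s
(generation tasks) and 7–27 s (matching tasks) as conventions and requires
the caller to choose. A rank-deficient design (e.g. a POI spanning the
whole epoch, making the boxcar collinear with the spline basis) raises a
named error.

`scale_ftcd_li` divides LI, SE and CI by a display constant (6 by
convention brings typical values near ±1).

**CI calibration caveat.** Conventional OLS standard errors are valid
when residuals are independent. After heart-cycle integration all samples
within a cardiac cycle are identical, so on fully pipeline-processed data
the SEs are anticonservative. Calibration (≈95% null coverage over 200
simulations) is therefore verified on directly generated epochs with iid
noise, where the model's assumptions hold; full-pipeline simulations
assert sign recovery of the injected effect, which is robust to SE
underestimation. Users comparing fTCD CIs with fMRI CIs should treat the
fTCD intervals as optimistic.

## Categorisation and agreement

Left iff CI lower bound > 0, right iff upper bound < 0, else bilateral; a
bound exactly at zero counts as including zero. The rule uses only the
CI, never the point estimate, and is invariant under positive rescaling.

Between-method agreement: Spearman's rho (average ranks for ties — LIs
can tie at 0 on degenerate inputs), with a percentile bootstrap CI over
1,999 case resamples (odd count → unambiguous percentile indices); the
resample index table is drawn in a single documented call so the CI is
reproducible from the seed. Resamples with a constant vector have
undefined rho and are excluded from the percentiles. The report adds a
3 × 3 category cross-tabulation and the percentage bilateral per method.

## Synthetic data: what it does and does not emulate

`generate_tmap` places mirrored hard-edged spheres with independent
left/right amplitudes on a symmetric 32³ × 2 mm grid (a desk-scale
stand-in for standard 2 mm template grids), optionally smooths (Gaussian,
FWHM in mm, applied after blob placement and before noise; default off so
noise-free maps have exactly constant homologous differences), then adds
iid Gaussian noise. It emulates: lateralised activation, bilateral
symmetric activation, and asymmetric *deactivation*. It does not emulate
spatial noise correlation, anatomical asymmetry (every voxel has a
homolog), or realistic cluster shapes — so tests passing here show
algorithmic correctness, not robustness to template asymmetry.

`generate_cbfv` builds each channel as
`base · (1 + 0.2·cos(2π·HR·t) + (response + δ·POI·[left] + noise)/100)`:
a raised-cosine pulse train at 70 bpm, a shared smooth task-locked bump
(8% peak over the cue+task period of a 5/20/25 s trial structure, 23
trials), a lateralised offset δ on the left channel inside the POI, iid
Gaussian noise (SD 1%), and optional spike artefacts. It does not emulate
respiratory modulation, heart-rate variability, probe drift, or
autocorrelated physiological noise. One consequence of iid noise: the
0.0001–0.9999 quantile flags always tag the most extreme ~0.02% of
samples, and since 42 s epochs tile most of the recording, a few trials
per run are artefact-flagged — the flagging rule operating as specified
on tail samples rather than on true artefacts.

`generate_study_cohort` (30 subjects) combines a strong symmetric focal
peak, a broad weakly lateralised region (gap ~ N(0.5, 0.25) against
noise SD 1) and an asymmetric deactivation region. This reproduces the
regime in which the two fMRI estimators diverge: the suprathreshold LI
is lateralised at low thresholds but symmetric at high ones, widening the
threshold-weighted CI, while the mirror method pools activation and
deactivation asymmetry into a narrow difference-score CI — so the
threshold-bootstrap method categorises more subjects bilateral.

## Problem sizes used in the automated checks

Simulation-based checks run at desk scale, chosen to exercise every code
path with known ground truth: 16³ and 32³ grids; 100-seed sign-recovery
and 200-seed coverage simulations with 6–10 trials per recording;
30-subject cohorts. Statistical assertions use tolerances derived from
the binomial/Monte-Carlo error at those sizes.

## Known limitations

- No nonlinear within-subject left-right anatomical alignment; the mirror
  method inherits the symmetric-template assumption and drops unpaired
  voxels.
- No cluster-level inference on difference maps.
- The threshold-bootstrap implementation targets the published algorithm
  description, not bit-compatibility with the original MATLAB toolbox;
  its other LI variants (clustering, variance weighting) are out of
  scope.
- fTCD vendor formats are not parsed; input is delimited text.
- The legacy peak-window fTCD LI is not provided; the plain subtraction
  LI exists only as the reference implementation for the GAM's flat-limit
  identity.
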