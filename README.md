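# latmirror

Hemispheric laterality indices (LIs) for language neuroimaging, from two
modalities and by three estimators, with confidence-interval-based
left/bilateral/right categorisation and between-method agreement
summaries.

## Who this is for

Researchers quantifying which hemisphere dominates a task — for studying
atypical language lateralisation, for comparing measurement methods, or
for planning analyses where "bilateral language" must be defined
statistically rather than by an arbitrary cutoff.

## The estimators

**Threshold-bootstrap ("toolbox") LI** — from a volumetric t-statistic map
registered to a left-right-symmetric grid. The conventional index

LI = (L − R) / (L + R)

(L, R = summed suprathreshold statistic values per hemisphere) is computed
across 20 equally spaced thresholds from 0 to the ROI maximum. At each
threshold, 100 resamples (with replacement, 25% of values) per side form
100 × 100 = 10,000 LI values; thresholds leaving fewer than 10 voxels on
either side are discarded. Per-threshold 25%-trimmed means are combined by
a threshold-weighted mean, and the 95% CI is read from the
threshold-weighted pooled histogram of trimmed bootstrap LIs. Only
positive values pass a threshold, so asymmetric *deactivation* is
invisible to this estimator — and with negative inputs the conventional
index is unbounded (L = 2, R = −1 gives LI = 3).

**Mirror LI** — flip the map across the mid-sagittal plane, subtract
homologous voxel values (left minus right), and summarise the difference
scores by drawing 1,000 subsamples of 5% of the homologous pairs: the mean
of the subsample means is the LI and their 2.5th/97.5th percentiles the
95% CI. Threshold-free; uses every value regardless of sign, so
lateralised deactivation contributes.

**fTCD GAM LI** — from bilateral blood-flow-velocity recordings of the
middle cerebral arteries. After downsampling, artefact flagging,
normalisation to percent of channel mean, heart-cycle integration,
epoching (−12 to 30 s), baseline correction (−10 to 0 s) and trial
rejection, an additive model with a B-spline smooth of epoch time, side
and period-of-interest (POI) main effects, epoch dummies and a side × POI
interaction is fitted by OLS; the interaction coefficient is the
percentage blood-flow difference between left and right specific to the
POI.

In all cases positive LI = left-dominant, and an individual is
left-lateralised if the CI's lower bound exceeds zero, right-lateralised
if the upper bound is below zero, and bilateral otherwise.

## Worked example

Synthetic ground truth: a mirrored spherical blob pair (radius 10 mm) with
left amplitude 4 and right amplitude 1 on a symmetric 2 mm grid, voxel
noise SD 1 — a strongly left-lateralised map.

```python
from latmirror import (Blob, TmapSpec, generate_tmap, exclude_midline,
                       build_difference_map, mirror_bootstrap, toolbox_li,
                       CbfvSpec, generate_cbfv, preprocess, gam_li, PoiWindow)

spec = TmapSpec(blobs=(Blob((14, 6, 4), 10.0, 4.0, 1.0),), noise_sd=1.0, seed=7)
volume, masks, truth = generate_tmap(spec)
roi = exclude_midline(masks[0])          # drop voxels within 5 mm of x = 0

mirror = mirror_bootstrap(build_difference_map(volume, roi), seed=7)
tb = toolbox_li(volume, roi, seed=7)

rec, _ = generate_cbfv(CbfvSpec(n_trials=23, delta_pct=6.0, seed=7))
fit = gam_li(preprocess(rec), PoiWindow(7, 17))
```

Output:

```
mirror : LI = 2.972  95% CI [2.445, 3.505]  -> left
toolbox: LI = 0.784  95% CI [0.579, 0.907]  -> left  (7 thresholds retained)
fTCD   : LI = 5.59%  95% CI [5.55, 5.64]  -> left  (13 trials kept)
```

The mirror LI is on the difference-score scale and recovers the true
amplitude gap (4 − 1 = 3) despite the noise; the toolbox LI is on the
bounded [−1, 1] scale; the fTCD LI recovers (attenuated by normalisation)
the injected 6% lateralised flow difference. All three categorise the
subject as left-lateralised. Display scalings (`scale_mirror_li`,
`scale_ftcd_li`) divide estimates onto a common axis without affecting
ranks or categories.

The same operations are available from the shell:

```bash
latmirror synth tmap --seed 7 --out work/
latmirror mirror  --map work/tmap.nii.gz --mask work/roi_0.nii.gz --seed 7 --out work/mirror/
latmirror toolbox --map work/tmap.nii.gz --mask work/roi_0.nii.gz --seed 7 --out work/toolbox/
```

Each run writes `result.json` plus a manifest (seed, parameters, input
digests, version) that makes it bit-reproducible.

## Scope

The package starts from statistic maps already in a symmetric standard
space and from marker-annotated velocity recordings: first-level GLM
fitting, registration, smoothing and vendor file formats are out of
scope, as are atlas ROI masks (masks are user-supplied NIfTI files; the
package ships only synthetic ones). See `docs/methods.md` for the model
details, parameter defaults and known limitations.
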