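# Methods

This note documents the models, the synthetic cohort, the numerical choices
and the limits of what the package's tests demonstrate.

## Problem and pipeline

Enlarged perivascular spaces (ePVS) are fluid-filled spaces around
penetrating vessels, visible on T2-weighted MRI as small bright foci. The
package assesses ePVS burden in basal-ganglia crops ("parts": one
hemisphere × one axial slice, six per subject) with a two-stage cascade:

1. **Enhancement** — a U-Net image regressor trained with MSE to map the
   normalized part onto `minmax(image + mask)`, i.e. an image in which every
   ePVS pixel occupies the top of the [0,1] range. Dense pixel supervision
   lets this stage learn to *discriminate* ePVS from other bright structures.
2. **Quantification** — a five-conv-layer CNN with global average pooling
   and one linear unit, trained with MAE on counts normalized by the
   maximum count (48), applied to the enhanced image. Predictions are
   clipped to [0,1], rescaled to counts, rounded half-up, and graded on
   Potter's scale (0; 1–10; 11–20; 21–40; >40). A subject's grade is the
   maximum of its six part grades.

The cascade premise is an information asymmetry: the counting stage only
ever sees a scalar label per image, which is too weak a signal to learn
"what counts as an ePVS" from scratch in a small cohort, whereas the
enhancement stage learns it from dense masks and hands the counting stage a
standardized, confounder-suppressed image.

## Preprocessing conventions

* 16-bit raw intensities are normalized **per image** by min–max to [0,1]
  (not by dividing by 65535): scanner scaling is uncalibrated across
  acquisitions, and the target construction `minmax(image + mask)` presumes
  min–max framing. A constant image maps to all zeros (tie-break).
* Working size is 80 rows × 96 columns (bilinear, no anti-alias prefilter);
  the transpose convention is explicit in the code and configurable.
* Order of operations: crop → resize → normalize → target construction.
  Masks are resized nearest-neighbor and re-binarized at 0.5 so they stay
  binary; if resizing merges two puncta, the stored (pre-resize) count is
  kept as the label, since labels represent expert counts, not resampled
  masks.
* ROI extraction: a single-component ROI mask is used whole; a
  multi-component mask is split at the column midpoint of its bounding
  region and components are assigned to hemispheres by centroid
  ("left" = lower column indices).
* Counts map to labels as `c / 48`; the inverse multiplies by 48 after
  clipping the network output to [0,1]. The round trip is exact on 0..48.

## Networks and training

* **Enhancer**: depth-4 U-Net, 64 base filters (doubling per level), two
  3×3 conv + BN + ReLU per level, 2×2 max-pool, 2×2 transpose-conv up,
  skip concatenation, 1×1 conv + **sigmoid** head (guarantees [0,1]
  output; the target normalization implies the range but no activation).
* **Quantifier**: filters (64, 64, 128, 128, 256), BN + ReLU after each
  conv, 2×2 max-pool after layers 2 and 4 (GAP alone would make the net
  nearly resolution-blind at these receptive fields), GAP, one **linear**
  unit — MAE with a sigmoid head saturates at the rare extreme grades, so
  clipping at inference is preferred.
* **Recipe** (`paper` preset): Adam, lr 1e-4, batch 45, 500 epochs
  (enhancer) / 300 epochs (quantifier), augmentation by x/y flips, scaling
  0.9–1.1 and rotation ±15°, one geometric draw applied jointly to the
  input and an image target; count labels pass through unchanged.
* **Per-fold cascade**: the quantifier for fold *k* trains on images
  enhanced by fold *k*'s enhancer; no test subject of a fold enters either
  model's training set.
* The training engine is a small numpy implementation (im2col GEMM
  convolutions, explicit backprop, Adam). Everything is float32; seeded
  runs are bit-reproducible on a fixed backend/thread configuration, which
  is the determinism contract the tests assert.

### CPU-scale presets

The full-scale recipe is impractical on one CPU, so two reduced presets are
provided and used throughout the test suite:

| preset | U-Net | quantifier width | lr | epochs (enh/qua) | batch | augmentation |
|---|---|---|---|---|---|---|
| paper | depth 4, 64 filters | 1 (64..256) | 1e-4 | 500 / 300 | 45 | flips + scale + rotation |
| desk | depth 4, 16 filters | 1/4 | 1e-4 | 50 / 30 | 16 | flips + scale + rotation |
| mini | depth 2, 8 filters | 1/8 | 2e-3 | 60 / 60 | 16 | flips only |

The `mini` preset trades capacity for optimization speed (higher learning
rate, flips-only augmentation keeps geometry exact at very small n). The
package's end-to-end study (`evaluate.run_cascade_study`) runs `mini` on a
12-subject phantom cohort at half working resolution (40×48, with phantom
geometry scaled by the same factor) — sizes chosen so the full
cross-validated experiment completes in minutes on one CPU.

## The phantom cohort

`pvscade.phantom` generates seeded cohorts with the statistical structure of
the study data: six parts per subject; per-part counts drawn grade-first
from the empirical grade distribution of the 456-image cohort
(4, 244, 138, 55, 15)/456 — heavily skewed to grades 1–2 — then uniform
within the grade's bracket (grade 4: 41..48).

Each part is rendered as:

* **Tissue background**: smoothed Gaussian random field (σ = 6 px) around a
  tissue mean, times a smooth multiplicative bias field (amplitude 0.15,
  σ = 20 px), plus i.i.d. Gaussian noise — so σ_noise is nonzero and
  estimable for CNR.
* **Acquisition variability**: per-part multiplicative jitter on tissue
  mean (±20%), texture amplitude (±40%), noise (±40%) and ePVS brightness
  (±20%), emulating uncalibrated inter-scan scaling.
* **ePVS puncta**: anti-aliased ellipses, radius 1.2–3.0 px at the default
  120×140 part size, eccentricity ≤ 2:1, brightness 0.12 of the dynamic
  range (≈2.6 texture SDs — conspicuous but subtle, as on real T2).
  Placement is rejection-sampled with ≥2 px clearance between mask
  boundaries so the stored count is exactly the number of 8-connected mask
  components; bounded retries, then an explicit placement error.
* **Confounders**: Poisson(4) larger, elongated, brighter hyperintense
  structures (vessel/lacune-like; radius 3.5–6 px, eccentricity ≤ 4:1,
  1.0–1.6× the puncta brightness) that are *not* in the ground-truth mask.
  These encode the clinical difficulty the cascade addresses: raters must
  distinguish ePVS from similar-appearing lesions, and without such
  structures counting from raw images is trivially easy (the mean intensity
  almost determines the count) and enhancement has nothing to contribute.

Parts are emitted larger than the working size (default 120×140 → 80×96;
desk scale 60×72 → 40×48) so resizing is a real resampling step. A separate
whole-slice emitter with two elliptical hemisphere ROIs exists to exercise
ROI cropping.

**What the phantom does not emulate**: real anatomy (no basal-ganglia
structures, no partial-volume CSF spaces), 3D continuity across slices,
rater noise in the labels (counts are exact), and scanner-specific noise
spectra. Passing tests therefore demonstrate that the pipeline's mechanics
and its ordinal claims hold under the stated statistical regime — not
clinical performance on patient data. Absolute clinical figures depend on
the cohort and scanner and cannot be reproduced synthetically; the package
asserts the *orderings* instead (every baseline < learned enhancement in
CNR; learned enhancement lowers cross-validated MAE versus raw images and
versus predicting the mean).

## Evaluation choices

* **CNR regions**: the CNR definition names "signal", "surrounding
  area" and "background" without fixing a geometry; the package uses surround =
  3-px dilation ring around the mask, background = an 8-px frame at the
  part border (6-px at desk scale) excluding signal and ring. CNR is
  invariant to affine intensity rescaling applied to the whole part.
* **ICC**: two-way random-effects, absolute-agreement, single-measure
  ICC(2,1) with an F-based 95% CI, computed on grades at image and at
  subject level; a consistency form ICC(3,1) is available. Agreement was
  chosen because the comparison is predicted-vs-expert rating on the same
  scale, where systematic offsets should count against the model.
* **Rounding**: real-valued count predictions are rounded half-up before
  grading (brackets are integer-defined).
* **Folds**: seeded uniform shuffle of subjects into k=4 folds, sizes
  differing by ≤1, no grade stratification.
* Parts with a zero count (or an empty resized mask) are excluded from mean
  CNR — CNR is undefined without a signal region; they still count for MAE
  and accuracy.

## Known limitations

* The numpy engine is single-device and memory-bound; the `paper` preset is
  provided for fidelity but is only practical on hardware well beyond one
  CPU core.
* Bitwise reproducibility holds within one BLAS/thread configuration, not
  across backends.
* CLAHE's CNR gain on phantom parts is marginal (it equalizes background
  texture upward along with the signal), mirroring its characteristically weak CNR
  gain on small bright lesions; at some parameter settings it can fall below the raw-image CNR on
  individual parts — assertions about baselines are therefore on cohort
  means.
* The phantom's confounder and brightness parameters are plausible, not
  fitted to scanner data; no public size/shape statistics were available
  for calibration.
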