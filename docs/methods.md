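# Methods

## The screening model

The package implements a hierarchical screening pipeline for glaucomatous
optic neuropathy (GON) in fundus photographs. Its core assumption is the
clinical one: GON is expressed in the geometry of the optic nerve head —
cup enlargement relative to the disc, loss of the normal ISNT ordering of
rim widths (inferior ≥ superior ≥ nasal ≥ temporal), and wedge-shaped
retinal nerve fiber layer defects (RNFLD) — so a diagnosis built from
those measured quantities is interpretable by construction.

The stages, and the contracts between them:

- **Pre-diagnosis classifier** → glaucoma probability p_pre for the whole
  image. Label = glaucoma iff p_pre ≥ 0.8 (ties to glaucoma). The high
  threshold deliberately trades sensitivity of this *internal* stage for
  specificity, because a glaucoma pre-label routes the image to a cup
  segmenter that tends to draw larger cups; a low threshold would inflate
  the final false-positive rate.
- **Segmentation** of disc, cup, RNFLD per pixel. Two cup models exist:
  general (trained on all eyes) and glaucoma-specific (trained on
  referable eyes only); the pre-label selects between them. Disc and
  RNFLD segmentation never depend on the pre-label, which makes the
  hierarchy property testable: flipping the pre-label may change the cup
  mask only. The cup is intersected with the disc on every path.
- **Rim features.** CDR(θ), θ = 0…359°, is the ratio of distances from the
  disc-mask centroid to the outermost cup and disc boundary crossings
  along the ray at θ, sampled at 0.25 px steps, clipped to [0, 1], zero
  where the ray meets no cup. MCDR is its mean. The ISNT score is the
  inner product of the standardized profile with a standardized
  normal-eye baseline, divided by 360 so it is bounded in [−1, 1] by
  Cauchy–Schwarz; a constant (degenerate) profile scores 0.
- **Decision layer.** Linear SVM on (MCDR, ISNT score); Platt-style
  logistic calibration of the signed margin gives p₁; decision tree
  (RNFLD ⇒ glaucoma; else the side of the line, with on-the-line called
  normal); fusion p = (1+p₁)/2 with RNFLD else p₁; confidence regions by
  thresholds on p (reliable normal ≤ 0.2 < suspicious < 0.8 ≤ reliable
  glaucoma).

## Conventions that had to be chosen

Several constructions are under-determined by the clinical description;
the package fixes them once and records them in serialized metadata:

- **Angle frame.** 0° = superior, clockwise positive, 90° = nasal, 270° =
  temporal, in a canonical right-eye frame; left-eye profiles are
  mirrored into it on computation so one baseline serves both
  lateralities. Clock-hour sectors map as 1 hour = 30°, so the vertical
  sectors "11–1 o'clock" and "5–7 o'clock" are [330°, 30°] and [150°, 210°].
- **Ray origin** is the disc-mask centroid (not the cup centroid), and
  boundary crossings are the *outermost* mask-to-background transitions.
- **VCDR** is the ratio of vertical pixel extents of cup and disc along
  the image column through the disc centroid.
- **Normalization of the ISNT inner product** by the dimension, and
  standardization of the baseline *after* averaging, make the score a
  correlation-like quantity with self-score exactly 1. Scores are only
  comparable within one convention; the serialized baseline carries a
  convention tag.
- **Boundary orientation**: the margin is positive on the glaucoma side;
  with any realistic cohort the fitted ISNT weight is negative, so higher
  ISNT at fixed MCDR moves an eye toward the normal side.
- **Decision-line features.** The SVM and its calibration are fitted on
  (MCDR, ISNT) features computed by running the *trained* hierarchy back
  over the training cohort, not on ground-truth-mask features. This keeps
  the calibrated p₁ on the same feature distribution the evaluation eyes
  produce; calibrating on clean annotation-derived features makes p₁
  overconfident where segmentation error pushes normals across the line.

## Trainable models

The classifier is a small multilayer perceptron over a 32×32 downsampled
copy of the image. Each segmenter is a per-pixel multilayer perceptron
over a feature stack computed on a 128×128 working grid: RGB at Gaussian
scales σ ∈ {0, 2, 4}, a local-contrast channel (σ=2 minus σ=10 brightness,
which separates broad dark RNFLD wedges from thin vessels and slow
illumination gradients), and normalized position. Probability maps are
binarized at 0.5; disc and cup keep their largest connected component,
RNFLD drops components below 64 working-grid pixels (an order of magnitude
smaller than any rendered wedge) and is then upsampled to the input
resolution. `TrainConfig(network_depth, base_channels)` sets the hidden
layout (layer i has base_channels·2^(depth−1−i) units; default (32, 16)),
`epochs` caps the optimizer's passes, and a single seed makes training
deterministic. All of this is exposed as scikit-learn estimators
(`FundusClassifier`, `FundusSegmenter`, `DecisionLine`) with the spec'd
operations as thin wrappers.

An `oracle_mode` bundle returns the generator's ground-truth masks
instead of model output. It isolates the geometry and decision layers
from segmentation error, which is how the parameter-recovery and
decision-logic properties are tested.

## The synthetic generator

`simulate` draws an eye as: elliptical disc (semi-axes 75–105 px
horizontally, ×1.0–1.15 vertically, centre within ±35 px of the canvas
centre on the canonical 512×512 canvas); an analytic rim profile
CDR(θ) = base level − superior dip − inferior dip + temporal boost
(raised-cosine bumps; inferior dip 0.10–0.16 deep, superior 0.55–0.85 of
that, so normals conform to the ISNT rule), plus defect bumps; optional
RNFLD wedges (12–30° wide, radially from the disc edge to 2.2 disc
radii); optional hemorrhage and peripapillary-atrophy distractors.
VCDR_true is derived from the final profile as (CDR(0°)+CDR(180°))/2,
which equals the vertical-extent ratio of the implied cup and disc.

Grading applies the clinical rules to the generative parameters:
*definite* if VCDR ≥ 0.85 or a localized notch (rim-ratio dip ≥ 0.15 deep
over < 60°, with or without a corresponding wedge); *probable* if
0.7 ≤ VCDR < 0.85, general rim thinning (dip ≥ 0.10 over ≥ 60°),
localized thinning (dip ≥ 0.10 over < 60°) in the vertical clock sectors,
any RNFLD wedge, or a hemorrhage; else *unlikely*. Referable = probable
or definite. The 0.15 notch depth and 0.10 thinning depth are modelling
choices — the clinical rules name the signs without numeric definitions —
chosen so that a notch is a conspicuous focal defect and thinning a
clearly sub-notch one; both are module constants.

The intensity model is deliberately minimal: disc brighter than
background, cup brighter than rim, wedges darker than the surrounding
retina, arcuate dark vessels, Gaussian noise (SD 5) and a slight blur.
Cohorts default to a 50/25/25 unlikely/probable/definite mix (roughly the
half-referable composition of a clinic-based screening set). What the
generator does **not** emulate: photographic artefacts, disc tilt, myopic
crescents, diffuse RNFLD, vessel biophysics, real colour statistics.
Passing tests therefore demonstrate that the pipeline's logic, geometry
and statistics are correct and that the hierarchy is learnable from
images with these contrasts — not clinical-grade performance on real
photographs.

## Numerical choices and degenerate inputs

- Profile standardization uses the population SD (divisor 360); an SD
  below 1e-12 is treated as a constant profile (zero vector, degeneracy
  flag, ISNT score 0).
- Dice of two empty masks is 1 (perfect agreement on absence) — needed
  for RNFLD-absent eyes.
- Clopper–Pearson intervals are exact beta-quantile intervals; the AUC
  confidence interval is formed on the logit scale with the
  Hanley–McNeil variance estimate and back-transformed, so bounds stay
  inside (0, 1).
- The rank-sum comparison uses the two-sided Mann–Whitney form with tie
  correction (exact for small tie-free samples).
- Empty disc masks, single-class cohorts, invalid thresholds and
  out-of-range probabilities raise immediately with stage-tagged errors.

## Problem sizes

The bundled evaluations run at the sizes a single CPU handles comfortably
while keeping every estimate stable: baselines from 500 synthetic
normals; ISNT discrimination with 100 vs 100 MCDR-matched eyes; parameter
recovery on 200 oracle-mask eyes; and the trained end-to-end evaluation
on 300 training / 200 evaluation eyes (the composition of a 400-eye
reader-study-style set, half referable), repeated over five seeds in the
test suite. Unit tests use smaller canvases (128–256 px) where only
relative geometry matters; the geometric oracles always run at 512.

## Known limitations

- Segmentation operates on a 128×128 working grid; mask boundaries are
  therefore quantized at ~4 px resolution on a 512 canvas. Disc/cup Dice
  ≈ 0.97–0.98 on synthetic eyes; fine RNFLD texture is below this
  resolution by design.
- The per-pixel models have no shape prior beyond connected-component
  post-processing; they are not a substitute for clinically validated
  segmentation.
- Confidence regions are fixed thresholds on the fused probability, not
  learned bands in the feature plane.
- Hemorrhage and atrophy are rendered and enter the *grade*, but are
  deliberately absent from the feature layer — the final diagnosis sees
  only MCDR, ISNT score and RNFLD, so hemorrhage-only probable eyes are
  invisible to the interpretable layer (they can still be caught by the
  pre-diagnosis stage routing and count against measured sensitivity).
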