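# Methods

`neuromontage` predicts a binary language outcome (impaired / healthy,
operationalised as a spoken-picture-description T-score below 60) for
stroke survivors from two modalities: a spatially normalised 3D T1
volume and three tabular clinical features identified a priori as
prognostic — initial aphasia severity (a five-level category including
unknown/unconscious), left-hemisphere lesion size in voxels, and
recovery time (months between stroke and assessment). This note
describes the models and procedures the package implements, the choices
made where the design was genuinely open, and what the synthetic test
bed does and does not establish.

## Image representations

**Stitched montage.** Sixty-four axial slices of the normalised volume
are tiled row-major onto one 2D canvas, always in the same order, so a
canvas pixel corresponds to a fixed brain location across subjects. For
scans whose axial slices are 79×95 voxels the 8×8 grid yields a 632×760
canvas. Canvases are area-downsampled (box filter) to 256×256 before
entering a CNN. Frozen conventions the representation needs but that are
not dictated by the method itself:

* the volume's third axis runs inferior→superior and the top-left tile
  is the most inferior selected slice, so the most dorsal slices occupy
  the last tiles — exactly the tiles later surrendered to glyphs;
* the 64 slices are picked evenly across the axial extent; an explicit
  index list can be supplied to reproduce any other selection;
* intensities are min–max normalised per volume *before* stitching, so
  glyph intensities added later are on a comparable scale across
  subjects;
* downsampling is area (box) averaging: constants survive exactly and
  thin glyph strokes are averaged rather than aliased away.

**Region images.** The atlas is pushed through the stitch layout
(`project_atlas`), giving per-region canvas masks, and/or used directly
in 3D. A region image packs the top-K regions of an importance ranking
at native resolution onto a fresh canvas by first-fit shelf packing in
importance order with 2-pixel gutters (the published figures show the
result but not the packing rule). Two extraction paths exist because
the source resolution is ambiguous in principle: `native3d` (default)
crops each region's largest-area axial slice from the voxel grid;
`canvas` crops the region's stitched-canvas footprint.

K is chosen by cross-validation over K ∈ {3..12} × three learning
rates, minimising the mean class-weighted validation loss — never
lock-box accuracy, which would overfit the held-out test. The selection
rule (argmin over K of the per-K best loss) is unit-tested on a
hand-built table.

**Hybrid images.** The three tabular features are rasterised as glyphs
into reserved image real estate: in stitched montages, the four tiles
of the most dorsal slices (rarely lesioned); in region images, a
reserved bottom panel split into three boxes. Encodings:

* initial severity → a categorical silhouette: square = severe,
  triangle = moderate, cross = mild, ellipse = normal, star =
  unknown/unconscious. Triangle/ellipse/star follow the published
  mapping; square and cross are this package's choice for the two
  unprinted categories (distinct silhouettes, configurable);
* left lesion size → a filled regular pentagon whose radius is a linear
  map of the clipped value into (r_min, r_max); r_min > 0 so a
  zero-lesion subject still renders a detectable symbol;
* recovery time → a pie slice of fixed geometry whose fill intensity is
  a linear map into (i_min, i_max), i_min = 0.2 > 0.

Clip bounds default to the 1st–99th percentile of the training split
(lock box excluded) so outliers cannot flatten the usable range.
Rasterisation is 4× supersampled then box-averaged, deterministic, and
strictly monotone: pentagon pixel area increases with clipped lesion
size, mean pie fill with clipped recovery time. All pixels outside the
glyph boxes are bit-identical to the base image.

## Classifiers

Three 2D architectures share one probability surface
(`predict_proba` = sigmoid of a single logit), so the evaluation
protocol and the explanation engine are architecture-agnostic:

* **lightweight** — six repeats of conv(3×3)→ReLU→maxpool(2), flatten,
  fully connected head; default widths 16-32-64-64-128-128 (the
  historical filter counts are unpublished; widths are configurable and
  the tests use 8-16-16-32-32-32 at 64×64 inputs); trained with RMSProp;
* **resnet18_finetune** — a ResNet-18 topology (7×7/2 stem, 3×3/2
  maxpool, four stages of two residual basic blocks, global average
  pool) with the single-channel input replicated to three channels and
  a one-logit head; trained with SGD. ImageNet initial weights require
  a local weights file; absent one, the `pretrained` flag raises and
  randomly initialised weights are used;
* **early_fusion_resnet18** — the pooled final-stage features
  concatenated with the three tabular values (severity as an integer
  code with "unknown" its own level; continuous features standardised
  with training-split statistics) before the head.

The models run on the package's own numpy engine (`neuromontage.nn`):
im2col convolution, overlapping max pooling, batch normalisation,
residual blocks, hand-derived backward passes, SGD and RMSProp. Every
layer's gradient is finite-difference checked in development; the test
suite asserts that one small optimisation step decreases a single
example's loss for each architecture. The engine is single-threaded
CPU code; widths, input side and batch size are the speed dials.

## Evaluation protocol

The cohort is split into **five groups balanced** on recovery time,
initial severity, left lesion size and outcome: subjects are sorted
into strata (outcome is the primary key, so its strata are contiguous;
categorical levels and quartile bins nest inside) and dealt round-robin
with one continuing pointer. Group sizes therefore differ by at most
one and per-group prevalence is as even as integer arithmetic allows
(34 impaired in 100 subjects → 6–7 per group). The fifth group is the
**lock box**: its labels live behind a guard object that raises on any
read before an explicit unlock, is unlocked exactly once at report
assembly, and counts accesses; the working label array additionally
carries a poison value (−1) for lock-box rows so accidental use in a
loss would fail loudly rather than silently leak.

Each model is trained by 4-fold cross-validation on the remaining four
groups (train on three, validate on one), for up to 200 epochs with
early stopping at the epoch minimising the class-weighted binary
cross-entropy validation loss (weights ∝ inverse class frequency of
the training split, normalised to mean 1; ties break to the earliest
epoch). The grid is three learning rates {1e-4, 5e-4, 1e-5} × twenty
seeds at full scale; the tests run reduced grids. After restoring the
best epoch, probabilities are recalibrated by **single-parameter Platt
(temperature) scaling** fitted on the validation split — a monotone
map, so AUC is unchanged — and the lock box is predicted once.

Metrics: accuracy, balanced accuracy (mean of sensitivity and
specificity), F1, and tie-averaged AUC (rank form, equal to the
trapezoidal ROC with tie averaging; verified against explicit pair
counting), overall and for the severe/moderate-severity subgroup
("unknown" subjects are excluded from the subgroup, retained overall);
a threshold sweep over 0.1..0.9; across-fold means ± 1.96·SE.
Single-class label vectors yield AUC = NaN with an explicit flag,
never a silent 0.

**Model comparison** uses the corrected resampled t-test: the variance
of the mean paired accuracy difference is inflated from 1/J to
1/J + n_test/n_train, compensating for the dependence induced by
overlapping training sets across folds, with Benjamini–Hochberg FDR
across a family of comparisons. The null simulation in the test suite
draws, per replicate, two equal-skill learners that threshold two
different, equally informative Gaussian features over J = 15 random
75/25 splits — a regime where the difference varies with the dataset
draw, which is what the correction compensates for; there the corrected
test's type-I error is close to nominal while the naive paired t-test
is severely inflated. When the difference between algorithms carries
little dataset-level variance the correction is conservative; that is
the documented cost of the adjustment, not a defect.

A baseline logistic regression on the three tabular features (fitted
with statsmodels' deterministic BFGS) is provided for reference.

## Region-importance explanations

The explanation engine is perturbation-based. For a target image S with
predicted class c, a **contrast image** S″ is the candidate-pool member
with the lowest predicted probability for c (ties to the lowest index;
a singleton pool scoring > 0.5 is accepted with a warning). A perturbed
image S′ replaces the pixels of a subset of atlas regions in S with the
same pixels from S″. Sampling ≥ 1000 subsets — all singletons, all
leave-one-out complements, uniform-size random subsets, plus always the
empty and full sets — and recording the classifier's probability on
each S′ yields a regression dataset. A **logistic surrogate** on the
binary replacement indicators is fitted by iteratively reweighted least
squares with a light L2 ridge (1e-3, intercept unpenalised) directly on
the probability-valued response; its per-region coefficients are the
importance scores, and per-record |surrogate − classifier| gaps are the
fidelity errors. **Counterfactuals** are the inclusion-minimal replaced
sets that flip the predicted class, found among observed subsets and
greedily shrunk via optional probing. Averaging scores over many
explained predictions (100 at full scale) and sorting descending gives
the key-region ranking; the sign convention flips with the predicted
class so that "importance" always means "supports the current
prediction".

The empty-set perturbation reproduces the target image bit-for-bit and
the full-set perturbation the contrast composite; recorded
probabilities match direct classifier calls up to float accumulation
order across batch shapes (≈ 1e-15 for BLAS-backed classifiers).

## Synthetic test bed

Because paired clinical volumes and outcome tables are not freely
distributable, every stage is tested on simulated data with known
ground truth:

* **atlas** — an ellipsoidal brain mask partitioned into Voronoi
  regions whose seed points alternate between hemispheres (midline at
  half the first axis); no region straddles the midline. Default 64³
  grid at a nominal 3 mm, 20 regions;
* **subjects** — smooth low-frequency intensity texture (Gaussian-
  filtered noise) inside the mask, 1–3 ellipsoidal hypointense lesions
  of 4–10 voxel radius placed with probability 0.7 in the left
  hemisphere (mirroring the left-lateralised relevance of language
  regions), plus Gaussian intensity noise (σ = 0.05);
* **tabular** — left lesion size recomputed from the mask (an enforced
  invariant); recovery time lognormal with mean ≈ 46 and SD ≈ 54
  months, matching the acquisition-delay distribution reported for the
  emulated cohort; severity from ordered thresholds on lesion burden
  plus reporting noise, with a configurable fraction (default 0.2,
  matching the reported missing rate) reassigned to "unknown";
* **outcome** — Bernoulli with logit = intercept + Σ wᵣ·(damage
  fraction of causal region r) + severity and recovery-time terms. The
  intercept is solved by root-finding on a deterministic probe sample
  so the expected impaired fraction hits the target prevalence
  (default 0.34, the reported skew); the Monte-Carlo check at n = 2000
  lands within ±0.03.

All randomness derives from (config seed, subject index); outputs are
bit-reproducible, and cohorts serialise to NIfTI + CSV + JSON.

What the generator does **not** emulate: MR physics, bias fields,
registration error, anatomically shaped parcels or lesions following
vascular territories, and the unknown joint distribution of severity,
lesion size and recovery time in real cohorts (only marginals are
matched; correlations are configurable, not calibrated). Passing tests
therefore establish that the pipeline is correct and that its
feature-selection and fusion mechanisms work when the generative
assumptions hold — not that the reported clinical accuracies transfer.

## Problem sizes used by the test suite

The published experiments (hundreds of subjects, ResNet-18, 200 epochs
× 3 learning rates × 20 seeds) are reduced to desk scale as the
package's own test conditions, frozen in the suite: the causal-region
recovery check uses 600 subjects, a 16-slice 4×4 montage at 64×64 CNN
input, the lightweight CNN (widths 8-16-16-32-32-32), one learning
rate (5e-4), three seeds, ≤ 30 epochs, and 16 explained predictions ×
1000 perturbations per seed; the hybrid-vs-image-only comparison uses
300 subjects, seven-region images on a 128×128 canvas with a 32-row
glyph panel, five seeds, ≤ 20 epochs. Both checks are directional or
rank-based, not accuracy reproductions.

## Known limitations

* The exact historical slice-selection rule, glyph sizes/positions, and
  the lightweight CNN's filter counts are unrecoverable from the
  published description; the package freezes documented, configurable
  stand-ins.
* The perturbation-subset distribution and surrogate regularisation of
  the original explanation tool are specified only in its own
  reference; the defaults here are stand-ins recorded in each
  explanation's metadata.
* The ResNet-18 adapter trains from random initialisation unless a
  local weights file is supplied; fine-tuning from ImageNet weights —
  worth ≈ 3 balanced-accuracy points in the published ablation — is
  not reproduced offline.
* Counterfactual search is exhaustive only over sampled and greedily
  probed subsets (exhaustive enumeration is feasible only for ≤ 12
  regions).
* The numpy engine is deliberately minimal: no dropout (the published
  protocol uses none), no data augmentation (argued harmful for
  spatially normalised lesion data), single-threaded CPU execution.
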