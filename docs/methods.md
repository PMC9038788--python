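# Methods

`bodycomp` implements a fully automated CT body-composition analysis at the
L3/L4 lumbar level with integrated, machine-learned quality control, and a
synthetic phantom generator that lets the whole pipeline be trained and
evaluated without clinical data. This note describes the models, their
parameters, the phantom's generative assumptions, and the numerical and
design choices made where the design was genuinely open.

## Pipeline

A case flows through four stages:

1. **Slice extraction.** The L3/L4 level is localized in the 3D volume by a
   segmentation detour: the single annotated disk-center coordinate is
   expanded into a ball-shaped training target (an isotropic Gaussian in
   physical space, binarized at a fraction of its peak), a small 3D
   encoder-decoder segments that ball, and the predicted blob is reduced to
   one axial slice index.
2. **Presence QC.** A univariate logistic regression on the log of the
   predicted blob volume decides whether the scan contains the L3/L4 level
   at all. Scans judged absent short-circuit the rest of the pipeline with
   an `absent_level` flag.
3. **Tissue segmentation.** The extracted 2D slice is segmented into
   background, skeletal muscle (SM), visceral adipose tissue (VAT) and
   subcutaneous adipose tissue (SAT) by a competitive dense
   encoder-decoder (CDFNet-style): feature maps at dense-block and skip
   junctions are merged by element-wise maximum rather than concatenation.
4. **Segmentation QC and post-processing.** A univariate linear regression
   maps the mean binary entropy of the muscle-class probability map to an
   expected muscle Dice score. Compartment areas (cm²) and the fatty muscle
   fraction (FMF — the share of SM-labeled pixels whose native HU falls in
   an adipose window) are computed from the predicted mask, and a cohort
   policy flags the lowest decile of predicted Dice.

Both networks are trained with five-fold cross-validation; inference
averages the softmax outputs of the fold models. Both QC models are fitted
on the cross-validation predictions of the very ensembles they accompany, so
a bundle always carries uncertainty models calibrated to its own networks.

Exclusion is advisory metadata: every input volume produces exactly one
report, and flagged cases are stratified, never dropped.

## Networks and training

The networks run on a small self-contained numpy CNN engine (`nets.py`):
im2col convolutions via BLAS matmul, 2x mean pooling, nearest-neighbour
upsampling, competitive (max) or concatenation merging, cross-entropy plus
soft-Dice loss, and Adam. Training is deterministic for a fixed seed and
thread count. Analytic gradients are verified against finite differences in
the test suite.

### 3D disk-blob extractor

* Resampling to (3, 6, 6) mm: native z resolution is kept because the task
  only needs z precision; in-plane content is coarsened aggressively.
* Label ball: sigma = 8 mm, threshold 0.5, i.e. radius
  sqrt(2 sigma² ln 2) ≈ 9.4 mm — the scale of an intervertebral disk. Both
  are configurable and no evaluation depends on their exact values.
* Architecture: plain U-Net-style encoder-decoder, widths (4, 8, 16),
  3 resolution levels, two 3×3×3 convolutions per block, concatenation
  skips. ~30k parameters.
* Patch-based training: patches of 32×16×16 voxels, 60% of draws forced to
  contain the target ball; flips in x and HU noise (sigma 20) as
  augmentation; HU clipped to ±1024 and z-scored per volume.
* Loss: CE + soft-Dice on the foreground. The foreground occupies ~0.1% of
  the voxels, so its CE weight is raised to 50 during the first two thirds
  of training and dropped back to 1 afterwards (together with a 0.3x
  learning rate decay); the early phase buys recall, the late phase lets
  the size-calibrated soft-Dice term set precision. 28 epochs, Adam at
  8e-3. A fold whose model collapses to the all-background solution
  (detected by empty predictions on its own training split) is retrained
  from a different seeded initialization, at most twice — tiny networks on
  a ~0.1% foreground occasionally need this.
* Inference: sliding windows with overlap 0.5 and Gaussian-weighted fusion;
  fold-softmax averaging; threshold 0.5; **largest connected component**
  post-processing (the target is a single ball, so stray islands at other
  disks are discarded); centroid of the blob rounded to a slice index, ties
  toward the inferior slice. An empty blob is a valid no-detection result
  and feeds the presence QC.

The centroid rule (rather than argmax of per-slice blob area) was chosen
because it is robust to voxel-level noise in small blobs; the inferior tie
rule makes rounding deterministic.

### 2D competitive dense segmenter

* Input: the native 96×96 phantom slice, HU clipped to a soft-tissue window
  of ±250 and z-scored per slice.
* Architecture: 3 resolution levels, widths (8, 16, 32), dense blocks of two
  convolutions whose junctions merge by element-wise maximum; skip
  junctions likewise. Setting `use_maxout=False` switches every junction to
  concatenation followed by a 1×1 transition back to the block width, so
  the ablation changes merging only and output shapes are identical.
* Loss: CE + soft-Dice averaged over the three foreground classes; 34
  epochs, Adam at 3e-3 with a 0.3x decay at two thirds; flip and HU-noise
  augmentation. Argmax ties break toward the lower class code, preferring
  background — a deterministic, conservative rule.

## Quality control

* **Presence model.** Feature: log(blob volume [ml] + 0.01). Positives are
  the cross-validation predictions on the full training volumes; negatives
  are predictions on a crop of each volume whose boundary stays at least
  10 mm from the disk center (side chosen by seeded randomness), giving a
  balanced two-class set. The fit is maximum-likelihood logistic regression
  with weak L2 regularization so perfectly separated data converge. The
  model is constrained monotone: a negative fitted slope (possible only
  when volume is uninformative) is projected to the intercept-only
  majority model, so a larger blob never lowers the presence probability.
* **Dice regressor.** Feature: mean over all pixels of the binary entropy
  −[p ln p + (1−p) ln(1−p)] of the SM-class probability (natural log,
  0 ln 0 := 0). A categorical-entropy mode over all classes is available;
  the binary SM mode is the default because muscle is the clinically
  decisive class. Ordinary least squares on the cross-validation
  (entropy, observed SM Dice) pairs; the residual SD and 95% confidence
  intervals of both coefficients are stored; predictions are clipped to
  [0, 1].
* **Policies.** The restrictive cohort policy excludes the floor(0.10 · n)
  cases with lowest predicted SM Dice, ties broken by case identifier. For
  single-case streaming, where a cohort quantile does not exist, an
  absolute threshold (default 0.924) is provided instead.

## The phantom generator

Each phantom is an axial stack (default 64×96×96 voxels at 3×1.5×1.5 mm —
desk-scale CPU training while keeping multi-slice geometry) with, per slice:
an elliptical body outline (radii jittered per case and per slice), a
subcutaneous fat ring, a muscle wall, a visceral interior of organ-like
tissue with elliptical VAT blobs, and a posterior circular column
alternating bone vertebrae (8 slices) with soft disks (2 slices). Per-tissue
HU values are Gaussian draws: air −1000, fat −95 ± 20, muscle 45 ± 15, organ
30 ± 15, bone 700 ± 100, disk 100 ± 30, fluid 10 ± 8. Pixels inside the
muscle wall become adipose-HU "intramuscular fat" with probability 0.10 but
keep the SM label, matching the annotation convention in which intermuscular
fat belongs to the muscle class; the true FMF of a phantom therefore tracks
that probability.

Exactly **one** disk is the designated L3/L4 target, and it carries a
geometric signature: it spans the full column width (other disks are
narrower, ringed by bone) and sits at the body "waist" (the outline narrows
around the target level). This stands in for the anatomical context a
clinical model learns from full lumbar anatomy and makes the target
learnable by a small network — and recoverable by a model-free oracle
(argmax over slices of disk-HU voxel count inside the column region), which
the tests use to validate localization independently of any training.

Artifact modes emulate the difficult cases of clinical cohorts: metallic
implants (HU ≥ 3000 core with alternating ±180 HU radial streaks at the
target level), anasarca (SAT ring thickened 1.6x and 35% of its pixels
replaced by fluid HU), and ascites (fluid pockets replacing visceral
tissue). Cohorts draw per-case seeds from a master seed; artifact flags are
Bernoulli draws at requested rates; a manifest suffices to regenerate any
case bit-identically.

What the phantoms do **not** model: organ anatomy, beam hardening and other
reconstruction physics, contrast phases, patient positioning, arms in the
field of view, hernias, or inter-annotator variability. Passing the
synthetic study therefore demonstrates that the pipeline's machinery —
label construction, training, ensembling, QC calibration, post-processing —
is correct and well-calibrated on data satisfying its assumptions; it does
not certify clinical performance.

## Numerical choices and degenerate inputs

* z indices are 0-based, arrays are (z, y, x), z runs inferior -> superior;
  volumes are reoriented on read. Physical positions are mm.
* Centroid and annotation rounding share one tie rule (toward inferior).
* A z-score guard (SD floor 1e-3) keeps constant slices (all air) finite.
* Probability maps renormalize after fold averaging and resampling; per-pixel
  sums are asserted to 1 within 1e-5.
* FMF uses native unclipped HU and is undefined (flagged, not crashed) when
  no pixel is labeled SM. Relative agreement is undefined when the reference
  value is 0.
* DICOM series with slice-spacing deviations beyond 5% of the median are
  rejected as geometry errors; mixed series are format errors.

## Study sizes

The default synthetic study trains on 40 phantoms with five-fold
cross-validation and evaluates on 20 held-out phantoms, plus a 50-phantom
end-to-end cohort with a 10% implant rate; these sizes keep the whole study
within a desktop-CPU run while leaving every fold at least 8 validation
cases for QC fitting. The acceptance script reruns exactly this study from a
single seed.

## Known limitations

* The CNN engine is CPU-only and deliberately minimal; at clinical
  resolution (512×512 slices, hundreds of slices) it would be impractically
  slow — the architecture is scale-reduced, not the method.
* The presence model uses the single log-volume feature; a hook for richer
  feature sets exists but is not exercised.
* The entropy feature averages over all pixels; restricting it to predicted
  muscle pixels is a plausible alternative that was not adopted (the
  all-pixel mean is simpler and already strongly rank-correlated with
  observed Dice on phantoms).
* Cohort-decile exclusion needs a cohort; the absolute-threshold fallback
  uses a default calibrated to nothing better than the restrictive decile's
  upper edge and should be recalibrated per deployment.
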