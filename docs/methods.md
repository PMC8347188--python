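# Methods

`vesselseg` implements a fully automatic hybrid segmentation pipeline for
the abdominal vascular tree in CT angiography (CTA): a rule-based expert
system, a convolutional encoder–decoder trained on the expert system's own
output, a workflow that combines the two, an evaluation-metric suite, and a
synthetic phantom generator that stands in for patient data. This note
documents the models, the parameters that matter, the numerical choices,
and what the synthetic experiments do and do not show.

## The segmentation problem

A contrast-enhanced abdominal CTA shows the arterial lumen as a bright
(~300 HU) tube, cortical bone (spine) even brighter (~700 HU), and
intraluminal thrombus — clot lining an aneurysm between lumen and vessel
wall — at soft-tissue intensity (~30–70 HU), barely distinguishable from
the surrounding tissue (~40 HU). Three binary masks are produced per
volume: spine (needed only to suppress bright bone), lumen, and thrombus.
All processing is slice-wise 2D with slice-to-slice propagation; volumes
are indexed `(z, row, column)` with spacing `(row_mm, col_mm, slice_mm)`.

## Expert system (rule-based pipeline)

Fully deterministic; every tunable lives in `ExpertConfig` and serializes
to YAML with all defaults written out.

* **Pre-processing.** Gaussian smoothing with a physical sigma
  (`smoothing_sigma_mm`, default 1.0 mm), converted per axis via the
  spacing. Identity at sigma 0.
* **Spine.** Threshold at `bone_threshold_hu` (200 HU), morphological
  closing with an ellipsoid of radius `spine_closing_mm` (2.5 mm) to
  bridge inter-vertebral gaps, then restriction to 26-connected 3D
  components whose centroid lies in the posterior half of the slice. An
  image with nothing above threshold yields an empty mask plus a warning —
  a recorded failure mode, not an error.
* **Lumen.** On the mid-volume slice, candidate seeds are 8-connected
  components inside the contrast window `lumen_window_hu` (150–600 HU),
  anterior to the spine centroid, at least `min_seed_area_mm2` (40 mm²),
  with eccentricity at most `max_seed_eccentricity` (0.85); the largest
  wins, ties broken by distance to the anterior midline (the aorta is
  prevertebral and near-midline). The seed is refined by a morphological
  active contour without edges (ACWE, Chan–Vese energy evolved by
  morphological operators — PDE-free, few parameters, numerically robust)
  for `acwe_iterations` (25) on the slice clipped to `lumen_clip_hu`
  (−100 to 500 HU) with spine voxels suppressed to 0 HU. The converged
  contour initializes the neighbouring slice, in both directions; a slice
  is accepted while its converged region's Dice against the previous
  contour is at least `propagation_overlap_min` (0.5). No admissible seed
  → a structured `lumen-not-found` status with an empty mask. The absolute
  HU window is the deliberate brittleness of the rule pipeline: a scan
  whose lumen falls below 150 HU defeats the seed search even though the
  lumen is still visible in relative terms.
* **Thrombus.** Per lumen-bearing slice, a morphological snake initialized
  with the lumen dilated by `thrombus_dilation_mm` (8 mm) evolves on a
  local crop around the vessel, clipped to a soft-tissue window
  `thrombus_window_hu` (−100 to 150 HU). Three preparation steps keep the
  region energy honest: values saturating the window (bone, bright lumen)
  are flattened to the local background median; the lumen plus a
  `thrombus_inpaint_margin_mm` (1.6 mm) partial-volume ring is in-painted
  with the annulus median so the snake settles on the crescent's outer
  soft-tissue edge rather than the strong lumen edge; and the crop gets a
  light extra smoothing (`thrombus_crop_smoothing_mm`, 0.8 mm) because the
  thrombus/background contrast (~10 HU) sits below the noise. The
  converged region minus the lumen is the thrombus; a slice whose
  candidate region has less than `thrombus_min_contrast_hu` (3 HU) mean
  contrast against the local background is declared thrombus-free, and the
  in-painted ring is re-filled geodesically wherever detected thrombus
  touches it. An empty lumen is an error: the snake is undefined without
  its initialization.

## Convolutional model

A symmetric depth-5 encoder–decoder with skip connections on single-channel
per-slice inputs, implemented directly on numpy (im2col convolutions,
exact backpropagation, Adam): per level two 3×3 convolutions with ReLU
(widths 64, 128, 256, 512, 1024 at full scale), 2×2 max-pooling down,
2× nearest-neighbour resize followed by a 2×2 convolution up with skip
concatenation, a penultimate 3×3 convolution to 2 channels, and a 1×1
head — sigmoid for binary models, softmax over 3 channels (background,
lumen, spine) for the multi-class variant. No batch normalization. This
configuration has exactly 31,031,685 trainable parameters (binary) and
31,031,691 (multi-class); both totals are asserted against an independent
closed-form per-layer sum. The "18 hidden layers" of the design are the
3×3 convolutions of the double-convolution blocks (10 encoder + 8
decoder), counted by introspection; the resampling convolutions and the
two output-block layers sit outside that count.

Inputs are prepared per model: optional in-plane Gaussian denoising
(`input_smoothing_px`), an HU display window, then per-slice
standardization. The spine and lumen models use a wide window (−200 to
800 HU); the thrombus model uses a narrow soft-tissue window (−50 to
150 HU) with 1.5 px denoising, mirroring how a radiologist windows a scan
to see low-contrast clot. Per-slice standardization makes the network
insensitive to global contrast scaling — the property that lets a model
trained on good-contrast images still localize structures on degraded
ones, and the root of the hybrid's robustness.

### Training protocol

Adam with the soft-Dice loss `1 − (2Σpt + ε)/(Σp + Σt + ε)` (ε = 10⁻⁶),
aggregated over the batch; for the multi-class head the loss averages the
foreground channels. Training stops at `max_epochs` or when the monitored
Dice — hard Dice at threshold 0.5 on a held-out 10% split — changes by
less than 10⁻³ for 3 consecutive epochs. Geometric augmentation (rotation
±10°, shifts ±5%, zoom ±10%, horizontal flip) is available and seeded;
everything, augmentation sampling included, is reproducible under the
training seed.

The full-scale protocol uses learning rate 10⁻⁵, appropriate for a
many-thousand-image corpus. The desk-scale profile (base width 8, 128×128
slices, a few hundred phantom slices) uses 10⁻³ — a small model on a small
corpus needs a proportionally larger step — and trains without
augmentation: the bootstrap corpus is already parameter-jittered, and the
lowest-contrast task (thrombus) needs its few epochs for the signal
itself.

Soft-Dice training on a rare structure whose contrast sits below the
noise is empirically bistable at this scale: a run either finds the
crescent features early or falls into the all-background attractor, where
the saturated sigmoid leaves no gradient to escape with, and a lifted run
can later deteriorate abruptly. The thrombus profile
(`thrombus_training_config`) therefore combines four standard remedies,
all deterministic under the training seed: small batches (2),
thrombus-bearing slices presented twice per epoch, returning the weights
of the best held-out epoch rather than the last one, and multi-start —
up to three further attempts when a run's best monitored Dice stays
below 0.2, where every attempt is a fully independent short run (fresh
initialization, data order and held-out split; successful runs peak
within ~5 epochs, so short attempts are enough). Run quality still
varies across seeds;
experiments that *select* a single deployed model do so by held-out Dice
across the bootstrap seeds, while method-comparison means always include
every seed. Cross-entropy warm-ups were tried and rejected: on a
3%-positive task they drive the sigmoid into confident emptiness before
the Dice phase begins.

## Hybrid workflow

The network supplies localization, the rules supply boundary precision:

1. The spine and lumen networks predict per-slice probability maps,
   thresholded at 0.5 (a value of exactly 0.5 maps to 1; only values
   strictly below are zeroed).
2. Predicted spine voxels are erased — set to 0 HU, a deliberate literal
   choice (water-like, not air) — from the volume.
3. The expert lumen segmentation is re-run on the filtered volume, with
   the network's largest predicted lumen component replacing the
   brightness-window seed search. The network mask is used as a seed only,
   never intersected with the result; the provenance (network vs
   expert-window seed) is recorded. If the network predicts no lumen
   anywhere the expert seed search is the fallback; only when both fail is
   `lumen-not-found` returned.
4. The thrombus network's thresholded prediction is post-processed:
   connected components (26-connectivity) whose 1-voxel dilation does not
   intersect the lumen are removed (a crescent touches but does not
   overlap the lumen — hence the dilation); then each axial cross-section
   of (kept thrombus ∪ lumen) is replaced by its moment-matched filled
   ellipse minus the lumen. The ellipse comes from the region's
   second-order central moments with a +1/12 pixel-extent correction per
   axis, so a rasterized ellipse maps back onto itself. Replacement
   happens only when the fitted ellipse reproduces the unsmoothed section
   with Dice above 0.6 (guarding genuinely non-elliptic sections) and
   below 0.98 (sections already indistinguishable from their ellipse are
   left untouched, which makes exact crescents fixed points). The per-slice
   (axial) reading of the elliptic interpolation is implemented; an
   alternative reading — interpolating between slices along z — is noted
   but not taken.

## Synthetic phantoms

`PhantomSpec` describes a stylized abdomen: a contrast-filled lumen tube
with a smooth sinusoidal centerline and an optional Gaussian aneurysmal
bulge along z; a crescent thrombus built as an outer disk whose centre is
offset from the lumen centre by half the maximal thickness (the classic
eccentric-lumen aneurysm cross-section: thickness tapers from its maximum
to zero at the internal tangent point, and the cross-section is exactly an
ellipse minus the lumen); a posterior spine column with one
inter-vertebral gap slice every 10 slices (making 3D connectivity
nontrivial); soft-tissue background; and a single additive Gaussian noise
field. Class means: background 40, bone 700, lumen 300, thrombus 50 HU;
with zero noise every class is exactly its mean. `contrast_scale` scales
the lumen-minus-background mean; the degraded (AMI-like) regime uses
contrast 0.4–0.6, slice thickness 2–3 mm and doubled noise (SD 30 HU),
versus the good-contrast (AAA-like) regime at contrast 1.0, 2 mm slices,
noise SD 15 HU. Default test grid: 128×128×32 at (0.8, 0.8, 2.0) mm; the
same code path serves 512×512. Generation is deterministic under the
spec seed, and dataset generation samples jittered specs and per-volume
seeds from one master seed.

What the phantoms do not emulate: organs and bowel gas, the iliac
bifurcation and visceral branches, stent-graft artefacts, beam-hardening
and correlated CT noise, and anatomical variability beyond the jittered
parameters. Passing on phantoms therefore demonstrates the *mechanics* of
the pipeline — seed robustness, the bootstrap loop, the direction of the
hybrid gain under contrast/noise degradation — not clinical performance.

## Evaluation metrics

Per (prediction, truth) pair: confusion counts; Dice `2TP/(2TP+FP+FN)`;
Jaccard `TP/(TP+FP+FN)`; sensitivity; specificity; volume similarity
`1 − |FN−FP|/(2TP+FP+FN)` (equivalently `1 − |V₁−V₂|/(V₁+V₂)`, asserted
in tests); and the symmetric Hausdorff distance between mask boundaries
(voxels with a face-neighbour outside the set), Euclidean, computed via
distance transforms and cross-checked against a brute-force all-pairs
oracle. Units are voxels by default with a millimetre variant scaling
index deltas by the spacing (both provided because published tables often
leave the unit unstated). Degenerate denominators are flagged, never
dropped: two empty masks score Dice 1 by convention (agreement on
absence), an empty prediction against a non-empty truth scores 0 — failed
slices are counted, not excluded. Method comparison uses a paired
two-tailed Student's t-test per metric (`t = mean(d)/(sd(d)/√n)`, n−1
degrees of freedom) over matched slices, emitting a mean ± SD / min–max /
p table; zero-variance differences are flagged degenerate, with p = 1 when
the methods are identical.

## Problem sizes in the test suite

The suite trains desk-scale models (base width 8, 128×128) on a bootstrap
corpus of 3 jittered clean phantoms (96 slices) labelled by the expert
system, for 3 seeds; evaluates expert vs hybrid on 12 degraded phantoms;
runs the expert system on 20 clean phantoms; and compares two binary
models against the multi-class variant at 64×64 over 3 seeds. The metric
oracles run on 1,000 random mask pairs. These sizes are the package's
chosen desk-scale experiment; the same code paths scale up by changing
the spec and config objects.

## Known limitations

* The thrombus/background contrast in the phantom (10 HU against 15–30 HU
  noise) makes thrombus the weakest link for both methods, as it is in
  practice; expert thrombus labels are imperfect (Dice ~0.5–0.7 against
  ground truth on clean phantoms), which is precisely the weak-label
  bootstrap regime the hybrid is designed around.
* Every thrombus-bearing phantom in the bootstrap corpus carries its clot
  inside the aneurysmal bulge, so a desk-scale detector partly associates
  bulge geometry with thrombus: a thrombus-free *aneurysm* can draw false
  positives. The negative control therefore uses the anatomically typical
  negative (a straight thrombus-free vessel); corpora that mix in
  thrombus-free aneurysms were found to destabilize desk-scale Dice
  training outright, so absence learning is an acknowledged gap at this
  scale.
* DICOM support covers standard single-frame axial CT series only;
  missing or contradictory geometry is a hard error, never a guess.
* The 2D slice-propagation design cannot follow a vessel that leaves and
  re-enters a slice (no branching topology).
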