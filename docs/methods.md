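# Methods

## Problem and model

After total knee arthroplasty (TKA), the flexion angle a patient can
actively reach — the knee range of motion (ROM), with 0° a fully straight
leg — is the standard rehabilitation endpoint.  The package classifies a
single side-on photograph of the isolated lower limb into clinically
thresholded ROM categories under two schemes:

* **four-class**, one label per maximal-effort attempt: standard flexion
  (ROM ≥ 125°, the target of high-flexion prostheses), substandard flexion
  (< 125°), standard extension (ROM = 0°), substandard extension (> 0°),
  coded 0–3;
* **six-class**: the nearest of the recovery milestones 0°, 25°, 50°, 75°,
  100°, 125°.

The pipeline is: grayscale conversion → global Otsu thresholding → strict
binarization (`dst = maxval` iff `src > thresh`, else 0) → nearest-neighbor
resize to a square network input in {0, 1} → a CNN → softmax over the K
classes.  Binarization is the design centerpiece: it reduces a photograph
to a silhouette, discarding illumination, skin tone and clothing texture,
which is what lets a small network trained on ~1,000 images generalize.

The network stacks six 3×3 convolutional layers (ReLU, with 2×2 max
pooling after layers 1, 2, 4 and 6), two dilated 3×3 convolutional layers
(rates 2 and 4, zero-padded to preserve spatial size; rate 1 would recover
plain convolution exactly), a squeeze-style channel-attention gate after
each dilated layer, and two fully connected layers.  Channel attention
computes the per-channel spatial mean M2 of the feature map M1, passes it
through a reducing map W1 (C → C/16), ReLU, an expanding map W2 (C/16 → C)
and a sigmoid to get gates M3 ∈ (0, 1), and rescales channels:
M4 = M1 · M3.  The training objective is cross-entropy
J = −Σᵢ Σ_c y_ic log hθ(xᵢ)_c.

## Synthetic data generator

No public dataset of post-TKA knee photographs exists, so the package
ships a first-class generator that emulates the acquisition setting: a
supine patient, the operated leg isolated against a plain background,
thigh and shank idealized as two thick segments (capsules) hinged at the
knee.  Ground truth (all joint coordinates and the flexion angle) is
stored per image.

Per-image nuisance parameters, drawn from fixed seeded distributions
(fractions of the canvas side, default canvas 240 px):

| parameter | distribution | rationale |
|---|---|---|
| thigh length | U(0.28, 0.375) · canvas | side-view segment proportions |
| shank length | U(0.26, 0.35) · canvas | slightly shorter than thigh |
| limb half-width | U(0.030, 0.048) · canvas | length/width ratio ≈ 3–6, as in side-view photographs |
| global rotation | U(−15°, 15°) | camera roll / body alignment |
| translation | U(−8, 8) px per axis | framing variation |
| background level | U(10, 80) | bedsheet/backdrop intensity |
| foreground − background | U(60, 150), gap ≥ 40 enforced | guarantees Otsu separability |
| noise SD | U(0, 8) intensity units | sensor noise |
| Gaussian blur σ | U(0, 1.5) px | focus/motion blur |
| occlusion fraction | U(0, 0.25) of limb pixels | clothing partially covering the limb, below the severity that would exclude an image |

Rendering order is fixed: silhouette → blur → noise → occlusion → clamp to
[0, 255].  Per-record seeds derive from (global seed, record index) only,
so datasets are byte-reproducible and order-stable.

Angle sampling realizes each label's clinical range: flexion attempts draw
from [60, 150]°, extension attempts from [0, 40]° (plausible maximal-effort
ranges; no published angular distributions exist for either).  "ROM = 0°"
is applied with a 0.5° tolerance when labeling continuous angles, since an
exact zero has measure zero.  Six-class membership uses
nearest-milestone binning with midpoint edges (12.5°, 37.5°, …, 112.5°;
everything above 125° belongs to the 125° class); sampled angles keep a
small margin from bin edges so a label re-derived from the 3-decimal
stored angle never flips.  Six-class images with milestones ≤ 25° are
treated as extension attempts, the rest as flexion attempts.

What the generator does **not** emulate: anatomy beyond two segments (no
foot, hip or prosthesis), cluttered backgrounds, perspective
foreshortening, soft-tissue deformation, or lighting gradients.  Passing
tests on this data therefore demonstrate that the pipeline's machinery is
correct and that the architecture can learn angle-thresholded silhouette
classification at the published sample sizes — not that the published
clinical accuracies transfer to real photographs.

## Verification against independent oracles

Every numerically substantive operation is checked against a second,
independent computation: Otsu's threshold against an exhaustive
256-threshold scalar scan (exact integer equality, with smallest-maximizer
tie-break; a constant image returns the constant); stored flexion angles
against an angle re-measured by skeletonizing the rendered silhouette and
fitting the two segment axes (≤ 1° over the full 0–150° range, measured at
canvas 480 where raster quantization contributes well under a degree);
every layer's backward pass against central finite differences in float64;
the metrics against a sample-level counting oracle and scikit-learn's
macro averages; the cross-entropy against the explicit double sum.

## Numerical and protocol choices

* **Framework.**  The network and its training are implemented directly on
  numpy (float32, NCHW): convolution by shift-and-GEMM over kernel taps
  (which yields dilation for free), 2×2 max pooling with ties routed to
  the first raster-order element, hand-derived backpropagation, and Adam.
  Gradient-check tests pin the calculus.
* **Grayscale** uses ITU-R BT.601 weights (0.299, 0.587, 0.114) with
  round-half-up.
* **Resizing** is nearest-neighbor so inputs stay strictly two-valued;
  bilinear would reintroduce the gray levels binarization just removed.
  Binarization happens at native resolution, before resizing.
* **Training protocol**: stratified 8:2 split (floor(0.8 nᶜ) per class to
  training), batch 16, learning rate 2·10⁻⁴, Adam (β₁ 0.9, β₂ 0.999; the
  optimizer is a package choice — plain SGD is available by config), up to
  100 epochs by default, no augmentation, no schedule, no early stopping.
  Shuffling is reseeded per epoch from the run seed; the full pipeline is
  deterministic on one platform.
* **Loss reporting**: the objective is stated as a sum over samples; the
  package reports and minimizes the mean over the batch so the learning
  rate is batch-size independent (Adam makes the distinction immaterial
  for the updates themselves).  Probabilities are clipped at 10⁻¹² before
  logs.
* **Attention bottleneck** carries biases on both maps (conventional for
  squeeze-style blocks even when the defining equations omit them);
  reduction ratio 16.
* **Metrics**: per-class precision/recall/F1 macro-averaged (equal class
  weight, the standard choice under mild imbalance; micro and
  support-weighted variants are also emitted), accuracy as trace/total ×
  100.  A class never predicted (or never true) contributes 0 to the
  affected macro term, with a logged warning.
* **Degenerate inputs**: constant images threshold to their own value and
  binarize to all zeros; empty images, empty confusion matrices,
  out-of-range labels/thresholds and out-of-canvas poses are rejected with
  named errors rather than silently handled.

## Problem sizes used by the shipped checks

The end-to-end checks generate the four-class dataset at the published
composition 300/243/272/288 (1,103 images) and the six-class dataset at
139/206/219/221/204/165 (1,154 images — the published per-class counts;
they exceed the published 1,103 total, a discrepancy in the source that
the generator does not resolve: it honors whatever counts are requested).
These runs use a 64×64 network input and 20 training epochs — enough for
the test accuracy to plateau on this synthetic task — and a 240 px canvas.
The memorization check trains on 16 clean images at the default 128×128
input for 20 epochs; at learning rate 2·10⁻⁴ with a single batch per
epoch, total per-weight movement is bounded by 20 · lr, and the logit
sensitivity conferred by the 128-input flatten width is what makes
near-zero loss reachable inside that budget — at coarser inputs the same
check needs more epochs.

## Known limitations

* The numpy implementation is CPU-only and single-process; at the default
  128×128 input a full 100-epoch run at published scale takes hours, which
  is why the shipped end-to-end checks use 64×64 and 20 epochs.
* Determinism is platform-level: results are bit-reproducible on one
  BLAS/OS/numpy combination but may differ in the last float digits across
  platforms.
* The synthetic task is easier than the clinical one (clean backgrounds,
  guaranteed Otsu separability); accuracies on it are not estimates of
  clinical performance.
* Continuous angle regression is out of scope; the classifier only
  predicts thresholded categories.
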