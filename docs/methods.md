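# Methods

## The pipeline

The package implements a two-stage system for optic-disc (OD) analysis
in fundus-style images.  Stage 1 localizes the region of interest: a
compact ResNeXt-style classifier is trained on the binary
normal-vs-glaucoma task, and layer-wise class activation maps (CAMs) are
constructed from the rectified per-location gradients of the selected
class logit with respect to each block's activations.  The per-layer
maps are min-max normalized, bilinearly upsampled to the image frame,
and fused by element-wise maximum; the fused map is thresholded, reduced
to its largest 8-connected component, and the component's bounding box —
expanded by a margin, squared to the longer side, and shifted/clipped to
the frame — defines the crop handed to stage 2.  Stage 2 is a YNet: a
U-shaped encoder-decoder built from inception blocks that segments the
disc, plus a classification branch that scores glaucoma from the
disc-masked image and bottleneck features.  The two task losses are
minimized alternately with SGD-with-momentum.

Underlying assumptions: the disc is the brightest compact structure and
the class-discriminative region, so a classification CAM localizes it;
one connected disc per image; binary (normal/glaucoma) labels driven by
the cup-to-disc ratio (CDR).

## Synthetic study conditions

The generator (`gdynet.synthetic`) emulates the features of fundus
photographs that the pipeline depends on: a bright elliptical disc
(random eccentricity up to a 1.25 axis ratio, random rotation, center
jittered off-frame-center), a brighter concentric cup scaled by the CDR,
dark momentum-random-walk vessels, a smooth directional background
gradient, and additive Gaussian noise, emitted as RGB with the strongest
disc contrast in the red channel.  Defaults: 64×64 pixels; disc vertical
half-chord in [0.10, 0.20] of the frame; CDR uniform in [0.25, 0.45]
(normal) or [0.60, 0.85] (glaucoma) — disjoint ranges separated by the
labelling threshold 0.525 (the midpoint of the gap; the clinical
literature offers no single cutoff, so it is an exposed parameter);
intensities background 0.35, disc 0.75, cup 0.95; 4 vessels; noise SD
0.02.

Mask geometry is exact by construction: the disc and cup vertical
half-chords are snapped to half-pixel values (choosing among a few
candidate integer chord lengths the pair whose count ratio best matches
the drawn CDR, with the ellipse center row shifted by 0 or ½ pixel to
control count parity), so the CDR measured by counting mask rows through
the disc center equals the stored value within 2/image_size even at
64×64.  The stored `cdr` is the realized chord ratio; the drawn value is
kept in sample metadata.

What the generator does **not** emulate: photographic color/texture of
the retina, peripapillary atrophy, hemorrhages, illumination artifacts,
camera vignetting, or annotation noise.  Passing tests therefore show
that the pipeline's machinery (localization, joint training, metrics) is
correct and learnable under controlled conditions — not that the model
transfers to clinical images.

## Networks and numerical engine

All networks run on `gdynet.nn`, a reverse-mode autodiff engine over
NumPy arrays (im2col grouped convolutions, max/average pooling, bilinear
resizing as an explicit separable linear map, concatenation, sigmoid /
ReLU / leaky-ReLU).  Default precision is float32 (the training loops
are memory-bound on CPU); the finite-difference gradient tests switch
the engine to float64 via a context manager and probe random weight and
activation coordinates with step 1e-7 (piecewise-linear ops make larger
central-difference steps noisy).  Every layer's backward pass, including
the normalization layers, is covered by these oracles.

Stabilization choices (the source architecture does not specify
normalization): group normalization after each inception block and each
ResNeXt-block merge, leaky ReLU (slope 0.01) inside those blocks, and
gradient-norm clipping at 10 in the optimizer.  Without them,
normalization-free SGDM training collapsed into dead-ReLU constant
predictors at any workable learning rate; with them, single-sample
overfitting reaches Dice ≥ 0.99 within ~50 iterations across seeds.

The classification branch follows the YNet design — disc-masked image,
2× average pooling, concatenation with upsampled bottleneck features,
stride-2 3×3 convolution, pooling, and two fully connected sigmoid
layers (hidden width 64) — with two measured deviations:

* **Pooling over the predicted disc support instead of the whole
  frame.**  The glaucoma cue is the cup-to-disc *area ratio*.  With disc
  area varying ~4× between images, frame-global averages of
  cup-evidence and disc-evidence are not robustly linearly separable (a
  logistic-regression probe on threshold-area features reached only
  0.76–0.84 test accuracy, versus 0.96–1.00 for ratio features), so the
  branch normalizes its pooled statistics by the predicted disc area.
* **Batch normalization on the pooled feature vector** (running
  statistics for deterministic inference, recalibrated exactly on the
  training set after the last epoch).  The raw pooled features have
  O(1e-3) scale and sample-to-sample spread, which leaves the sigmoid
  head on a plateau that SGDM cannot escape; standardizing the features
  restores O(1) gradients.

The disc mask used by the branch is the probability map binarized at
0.5 (hard, non-differentiable; the branch trains the encoder through the
bottleneck path).  A `soft_mask` flag replaces it with the probability
map itself, keeping the model differentiable end to end — the gradient
oracles use that path.

## Losses and training

`L_seg` is mean per-pixel binary cross-entropy between the predicted
disc probabilities and the mask, scaled by 1/σ with σ ∈ (0, 1] (default
0.5).  A literal background-weighted squared-error variant
`(1−y)·(y−p)²/σ` is kept for comparison only; it carries no foreground
signal and is not used.  `L_cls` is binary cross-entropy on the scalar
score.  Probabilities are clipped at 1e-7 before logarithms.
Optimization alternates at mini-batch granularity — odd iterations step
on `L_seg`, even iterations on `L_cls` (a `joint` mode sums both) — with
SGDM (momentum 0.9), L2 penalty `l2·‖Θ‖²` (gradient `2·l2·Θ`), and the
step schedule `lr0 / factor^(epoch // period)`.  Training is
deterministic under the (model seed, shuffle seed) pair.  The localizer
backbone and the YNet are trained separately (backbone first), matching
the two-stage layout.

Reference hyperparameters: 100 epochs, batch 128, lr0 0.001, momentum
0.9, L2 0.001, halving every 20 epochs.  The desk-scale study used by
the tests and the acceptance script runs 200 train / 50 test images at
64×64 with a 30-epoch, batch-16, lr0 0.1 configuration (same schedule
shape), a backbone of 4 blocks with cardinality 8 and base width 16
trained 30 epochs at lr0 0.05 (halving every 10), and a depth-4 YNet
with base 4 filters and an 8-channel branch convolution.  These sizes
were chosen once as the smallest configuration that trains stably on a
single CPU core; the CAM-depth ablation runs the same pipeline at 40
train / 16 test images and 6 epochs per variant.

## RoI extraction choices

Fusion uses the element-wise maximum of normalized CAMs (preserves
shallow-layer detail; mean fusion available for ablation).  The
binarization threshold defaults to 0.2 of the normalized maximum and the
box margin to 0.25 of the component side per side; the source method
states neither, and at 64×64 these defaults produce boxes that always
contained the disc in held-out runs (mean coverage 1.0) at the price of
generous box sizes.  An identically-zero CAM raises a localization
error; the dataset-level driver falls back to a centered crop covering
the middle half of the frame and flags the row.  The CAM class selector
defaults to the argmax logit (exposed as a flag).

## Evaluation metrics

Confusion-derived rates, Dice, and Jaccard follow their standard
definitions; rates with zero denominators are reported as explicit
missing values with reason codes, never as 0 or 1.  The structure
measure is `α·S_o + (1−α)·S_r` with α = 0.5: `S_o` compares
foreground/background means and dispersions against the ideal constant
map, `S_r` splits the frame about the foreground centroid into four
rectangles and area-weights a luminance/contrast/structure similarity
per rectangle; degenerate ground truths score `1 − mean(pred)` /
`mean(pred)`.  The enhanced-alignment measure bias-corrects both maps by
their global means, forms the alignment matrix
`2·dg·dp/(dg²+dp²)`, enhances it as `(align+1)²/4`, and averages over
all pixels (normalization by `w·h`, which makes identical non-degenerate
pairs score exactly 1).  For probability maps, the mean-over-thresholds
mode binarizes at `(t+0.5)/256` for t = 0…255 — on an already-binary map
every threshold reproduces the map, so the mean equals the
single-threshold value exactly.  ROC/AUC use rank-based (Mann-Whitney)
tie handling via scikit-learn; an O(n²) pairwise oracle checks it in the
tests.  Dataset aggregation is the unweighted per-image mean for
segmentation and pooled counts for classification.

## Known limitations

* Synthetic-only validation; no transfer claim to clinical fundus data.
* At 64×64 the fused CAM localizes coarsely: RoI boxes reliably contain
  the disc but are loose (often most of the frame), so stage 2 does much
  of the localization work implicitly.
* The hard disc mask blocks gradients from the classification loss to
  the decoder; only the soft-mask mode trains that path.
* Single-disc assumption: the largest CAM component wins; images with
  multiple bright structures of similar salience would need a different
  component rule.
* The NumPy engine is single-threaded and CPU-bound; it is sized for
  64×64 studies, not for full-resolution fundus photographs.
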