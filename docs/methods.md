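# Methods

## Problem setting

Dermoscopic lesion archives are heavily skewed: in the seven-class
setting this package targets, the majority class (melanocytic nevi)
holds 66.95 % of the 10,015 images. A classifier trained naively on
such data collapses onto the majority class. The package implements a
complete treatment-and-model pipeline — rebalancing augmentation, three
multi-backbone fusion architectures with attention, a two-phase
fine-tuning protocol, a one-vs-rest metric suite, and gradient-based
saliency — together with a synthetic data generator so the whole
pipeline is exercised at desk scale.

## Preprocessing

Images are resized to a fixed target (default 450 rows × 600 columns)
with nearest-neighbor interpolation, then min-max normalized,
`(X − X_min) / (X_max − X_min)`. The default normalization range is the
fixed 8-bit one (0–255): per-image scaling would alter contrast
relationships between images, so the per-image mode (where a constant
image maps to zeros by convention) sits behind a flag. Resizing precedes
normalization; for nearest-neighbor interpolation the order is
observationally irrelevant, but it is fixed for reproducibility.
Float inputs already in [0, 1] are quantized back to the 8-bit grid
first, which makes the operation idempotent up to round-trip
quantization.

## Rebalancing treatments

**Rotation upsampling.** Every non-majority training image is joined by
its left–right mirror, up–down mirror, and their composition (a 180°
rotation). Originals of *all* classes are retained, so minority classes
quadruple and the majority is untouched.

**Style-transfer allocation.** After rotation, the per-class deficit
ratio against the majority count `r_i = (N_maj − N_i) / N_i` selects a
branch: for `r_i ≥ 1` each of the class's images spawns `⌊r_i⌋` styled
copies; for `r_i < 1` exactly `N_maj − N_i` uniformly chosen images are
styled once each, closing the gap exactly. Flooring is deliberate and
leaves small residual deficits in the `r_i ≥ 1` branch (e.g. a class of
836 against a majority of 4,291 plans 4 additions per image and ends at
4,180, not 4,291); the plan object records `n_before`, `num_add`,
`num_sub` and the predicted `n_after`, and execution is tested to hit
`n_after` exactly. Style sources are drawn from the same class without
replacement, excluding the content image itself (the scheme is silent on
self-pairing; exclusion avoids degenerate no-op transfers). When a class
is too small to supply `num_add` distinct styles, sampling falls back to
replacement with a logged warning.

**Stylization backend.** The default stylizer is a statistical color
transfer: content and style images are mapped to CIE Lab (a decorrelated
luminance/chrominance space), each channel of the content is affinely
matched to the style's mean and standard deviation, blended with the
original by a `strength` in [0, 1] (default 1.0, maximizing sample
diversity), mapped back to RGB and clipped. A zero-variance channel on
either side keeps the content statistics. Backends are pluggable through
a registry keyed by name, so a neural stylizer can be substituted
without touching the planner; the statistical backend keeps the package
self-contained and the count semantics identical.

**Class weights.** `w_i = n_samples / (n_classes · count_i)`, satisfying
`Σ w_i · count_i = n_samples`. Treated as an alternative to resampling,
not an addition — the trainer accepts either balanced data or weights.

**Pixel perturbation.** An ablation-style alternative: minority images
are duplicated with all channels shifted by a random ±v, v drawn without
replacement from `[1, ⌊deficit / (2 · n_classes)⌋]` on the 8-bit scale
(the pool resets with a warning when exhausted), clipped to the valid
range. Deficits are measured post-rotation.

## Fusion architectures

Branch backbones emit feature maps of possibly different geometry; for a
450×600×3 input the three reference extractors give (12, 17, 2048),
(12, 17, 1536) and (14, 19, 2048). Three strategies reconcile them:

* **conv_reduce** — branches with larger spatial maps pass through one
  valid 3×3 stride-1 convolution (output size `(W − F + 2P)/S + 1`,
  so 14×19 → 12×17), preserving the branch's channel count (only the
  kernel geometry is fixed by the design; keeping channels adds no new
  bottleneck), then channel concatenation → CBAM → GAP → dense → softmax.
* **zero_pad** — smaller maps are surrounded by rings of zeros
  (12×17 + one ring → 14×19; activation sums are invariant), then the
  same concat/CBAM/GAP/dense head. Geometry differences that are odd or
  anisotropic are a hard error pointing at the other strategy.
* **dense_concat** (classifier-level fusion) — each branch keeps its own
  CBAM → GAP → dense feature vector (default 256 units at full scale;
  the desk-scale configs use 32) and an auxiliary softmax head; the
  concatenated feature vectors feed a merged softmax head. The network
  exposes four outputs and the training loss is the plain unweighted sum
  of the four cross-entropies; the merged head is the model's
  prediction.

Parallel elementwise fusion (sum / mean / max) is provided for branches
with identical geometry, with a shape mismatch as a hard error — that
constraint is what defines parallel fusion.

**CBAM.** Channel attention: global average- and max-pooled descriptors
share a two-layer bottleneck MLP (reduction ratio 16 at full scale;
divisibility is enforced, and desk-scale configs use smaller ratios),
their sum passes a sigmoid and rescales channels. Spatial attention:
channel-wise mean and max planes are concatenated, convolved 7×7
('same'), sigmoid-gated. Placement: after the final backbone
convolution and before GAP in every strategy; for dense_concat the
toggle is per branch.

## Training protocol

Phase 1 freezes all backbone parameters and trains heads only; phase 2
unfreezes everything. The constraint `lr_phase2 ≤ lr_phase1` is
enforced. `TrainConfig` defaults (Adam, 1e-3 / 1e-5, batch 16, epochs
5 / 20) reflect the transfer-learning setting with pretrained backbones
the protocol was designed for. The desk-scale pipeline and the sklearn
estimator instead default to 1e-3 in phase 2 with 20 epochs: their tiny
backbones are randomly initialized, and at 1e-5 the backbone cannot move
off its initialization at all. Losses are accumulated in float64 so the
recorded total equals the arithmetic sum of the per-head losses exactly;
a NaN loss aborts with a diagnostic rather than training on.

Hard voting (the ensemble baseline): majority label across members, ties
broken by the highest mean predicted probability among tied labels, or
the smallest label index when no probabilities are available.

## Evaluation

All metrics derive from the K×K confusion matrix via one-vs-rest
counts. Because per-class "accuracy" `(TP+TN)/total` and recall
`TP/(TP+FN)` are easily conflated in this literature, both are reported
side by side, and the headline number is the overall (micro) accuracy —
the matrix trace over the sample count. Ratios with zero denominators
are reported as 0 and flagged rather than propagating NaN into weighted
averages. AUC is one-vs-rest with midrank tie handling (Mann–Whitney
form, equal to trapezoidal ROC integration); a class absent from the
evaluation set has undefined AUC and is excluded from the weighted
average. Weighted averages use evaluation-set supports.

## Interpretability

Grad-CAM: channel weights are the spatial means of the gradient of the
target score with respect to a chosen convolutional map; the heatmap is
the rectified weighted channel sum, min-max normalized to [0, 1] (an
all-zero rectified map is returned as zeros with a flag — no positive
class evidence at that layer). Grad-CAM++ weights each location by
`α = g² / (2g² + Σ_spatial A·g³)` (zero-division guarded), renormalized
per channel over the positive-gradient locations so the coefficients sum
to 1, then sums `α · ReLU(g)`. Gradients are taken with respect to the
pre-softmax score of the target class by default (the standard CAM
choice; it is invariant to shifting the other logits), with a flag to
differentiate the softmax probability instead. For dense_concat models
the per-branch maps are differentiated against the merged output, and
the default target layer is each branch's post-attention map. Heatmaps
are bilinearly upsampled for overlays with a fixed colormap.

## Synthetic data generator

Each image is a skin-tone background with Gaussian noise plus one
elliptical lesion whose boundary radius is sinusoidally perturbed
(`r(θ) = 1 + irregularity · sin(kθ + φ)`, k ∈ [3, 6]); lesion color is
drawn from a class-specific hue range with saturated, narrowly jittered
value so that the configured classes are linearly separable by color —
the property the learnability checks rely on. The default per-class hue
ranges are pairwise disjoint and spread around the hue circle. Class
counts default to the archive's printed counts and scale multiplicatively
(nearest-integer rounding, floor of 2 per class so 3:1:1 stratified
splitting stays feasible).

What the generator does *not* emulate: real dermoscopic texture, hair
and ruler artifacts, intra-class color overlap, and lesions whose
discriminative signal is morphological rather than chromatic. Passing
tests therefore demonstrate that the pipeline's mechanics (counts,
shapes, gradients, optimization, metrics) are correct, not that the
model architecture reaches any particular accuracy on real dermoscopy.

## Numerical choices and problem sizes

The compute core is a NumPy reverse-mode autodiff engine (float32
forward/backward, float64 loss accumulation). Convolutions are computed
as sums of strided matrix products over kernel offsets, keeping memory
at one feature map; 'same' padding follows the convention that splits
the total padding with the extra pixel on the bottom/right. Ties in max
reductions split gradient evenly; elementwise max routes gradient to the
first argument on exact ties. The reference backbone graphs omit
normalization layers (identity at initialization, no effect on
geometry) and are exercised with random weights only.

Tests and the acceptance script use deliberately small problem sizes —
tiny trainable backbones (maps like 12×17×8 from 56×76 inputs), 24–32 px
synthetic images, archive scale 0.02, and 4×4 images for the full
count-arithmetic replay of the augmentation table — chosen so the whole
suite exercises every code path in well under half an hour on one CPU.

## Known limitations

* The statistical stylizer transfers global color statistics, not
  texture; it is a different operating point from a neural stylizer,
  though the planner and count semantics are identical.
* The trainable backbones are small convolutional stacks, not the
  full reference architectures; the reference graphs are forward-only
  and used for geometry.
* Determinism holds within a NumPy/BLAS configuration; exact
  floating-point histories can differ across BLAS builds (count
  manifests and plans are integer-exact regardless).
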