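# Methods

This note documents the models, losses, metrics and generators the package
implements, the parameters that matter, and the design choices made where
the design was genuinely open.

## Detector architecture

Both variants are nano-scale one-stage anchor-free detectors.  Channel
widths follow the ladder (64, 128, 256, 512, 1024) scaled by
`width_mult = 0.25`, capped at `max_channels = 1024` before scaling, and
rounded up to multiples of 8, giving (16, 32, 64, 128, 256).  Block repeat
counts (3, 6, 6, 3) are scaled by `depth_mult = 0.33` with
`max(round(·), 1)`, giving (1, 2, 2, 1).  The backbone alternates stride-2
3×3 convolutions with C2f blocks (cross-stage-partial: a 1×1 split, n
residual 3×3 bottlenecks at half the output width, and a 1×1 merge of all
paths) and ends in an SPPF block (three chained 5×5 max-pools at half
width).  Backbone C2f blocks use residual shortcuts; neck C2f blocks do
not.  Every convolution is bias-free and followed by batch normalization
(momentum 0.03, eps 1e-3) and SiLU.

Heads are decoupled: per scale, a regression branch (two 3×3 conv cells
then a 1×1 projection, with bias, onto 4·`reg_max` channels — each box side
is a discrete distribution over `reg_max = 16` bins whose expectation, in
cell units, is the decoded distance) and a classification branch
(analogous, onto `nc` channels).  Branch widths: regression
`max(16, c_first/4, 4·reg_max)`, classification
`max(c_first, min(nc, 100))`, where `c_first` is the finest head scale's
channel count.  Classification projection biases are initialized to the
standard prior `log(5/nc · (s/640)²)` so that training starts from a
realistic background probability; regression biases start at 1.

### The enhanced (wildasm) variant

Three additions:

* **MHSA after SPPF.**  The 256-channel deepest grid is flattened to
  H·W tokens; four d×d bias-free projections form Q, K, V and the output;
  `h = 4` heads (`mhsa_heads` in the config) of dimension d/h use scaled
  dot-product attention with row-max-stabilized softmax.  There is no
  positional encoding, making the block permutation-equivariant over
  positions (exploited as a test), and no residual connection by default
  (`mhsa_residual` switches one on).
* **P2 branch.**  One extra upsample from the stride-8 top-down node,
  fused with the backbone's stride-4 features, a C2f, and a fourth
  detection head on the result (160×160 grid at 640 input).
* **Weighted fusion nodes.**  Every neck concatenation becomes a fusion
  node with one raw learnable weight per input (initialized to 1), passed
  through max(·, 0) and normalized as `w_i / (Σ w_j + ε)`, ε = 0.01; the
  scaled maps are then concatenated on channels.  Top-down nodes fuse two
  inputs; the stride-8 and stride-16 bottom-up nodes fuse three
  (downsampled lower node, top-down node, backbone feature); the stride-32
  node fuses two (downsampled node, post-attention backbone feature),
  since no separate top-down node exists at the coarsest level.
  Nonnegativity-by-clamping matches the fast-fusion convention this style
  of node comes from; ε = 0.01 is kept as specified for the block even
  though the original fast-fusion form uses 1e-4.

### Complexity accounting

`count_parameters` defaults to the deploy-time parameterization — each
conv+BN pair folded into a conv with bias — because that is what detector
summary tables conventionally report; the training-time count (BN affine
pairs present) is `fuse=False`.  The fixed 16-element expectation weights
of the distribution decoder are counted; running statistics are not.  For
the 10-class baseline this yields exactly 3,007,598 parameters and, at
nc = 80, the familiar 3,151,904.  `count_flops` sums k²·C_in·C_out·H_out·W_out
multiply–accumulates over all convolutions plus the four attention
projections (N·d² each), doubles, and reports GFLOPs to one decimal: 8.1
(baseline) and 12.5 (wildasm) at 640.  The attention score/value matrix
products are not linear layers and are excluded, matching the usual
profiler convention.  `n_layers` counts leaf modules and is informational
only; "layer" conventions differ across frameworks and are not comparable.

## Losses and assignment

Anchor points are cell centers `(i+0.5, j+0.5)·stride` across all head
scales.  Assignment is task-aligned: candidates are anchors whose center
lies strictly inside a ground-truth box; each box takes its top
`topk = 10` candidates by `t = s^0.5 · u^6` (s = predicted probability of
the box's class, u = IoU of the anchor's decoded box); an anchor claimed
twice goes to the box it overlaps most; soft classification targets are
`t` rescaled per box so its best anchor carries its best IoU.

* **Classification**: element-wise BCE on logits against the soft targets,
  summed and divided by the total target mass.
* **Box**: `1 − CIoU` on decoded boxes (IoU minus squared-center-distance
  over squared-enclosing-diagonal minus `α·v` aspect penalty with the
  standard constant `α = v/(1−IoU+v)`), weighted per anchor by its target
  score and normalized by the same mass.
* **DFL**: cross-entropy of each side's bin distribution against the two
  integer bins bracketing the target distance (in cell units, clamped to
  `[0, reg_max−1−10⁻³]` with a warning), linearly interpolated, averaged
  over the four sides, weighted and normalized as above.

Total = 7.5·box + 0.5·cls + 1.5·dfl (the defaults of the framework
generation this head design comes from; exposed in `LossGains`).

## Training protocol

SGD with momentum 0.937 and weight decay 5e-4 applied to matrix/conv
weights only; linear warmup over the first 3 epochs then a one-cycle-style
linear decay from `lr0 = 0.01` to `lr0·lrf`; global gradient-norm clipping
at 10.  Defaults `max_epochs = 5000`, `patience = 50`, `batch_size = 16`
mirror the stated experimental protocol; early stopping monitors the
validation loss literally (not a blended fitness) and halts after
`patience` consecutive epochs without improvement, returning the best
validation epoch's weights.  One seed drives initialization, shuffling and
augmentation; two runs with identical configs produce identical
trajectories.  Augmentation is horizontal flip only (off by default);
mosaic-style composition is deliberately not implemented to keep the suite
deterministic and small.  `workers` is accepted for config compatibility
but loading is in-process.

Early-stopping boundary semantics: "no improvement" means not strictly
below the best seen; with constant validation loss from epoch k the loop
stops at epoch k + patience exactly.

## Evaluation

Greedy per-class matching by descending confidence, one match per ground
truth, at the evaluation IoU threshold.  AP is the mean of the monotone
precision envelope sampled at 101 evenly spaced recall points; mAP50
averages AP over classes with ground-truth support; mAP50–95 averages over
IoU ∈ {0.50, 0.55, …, 0.95} first.  Evaluation decoding uses confidence
threshold 0.001 and class-aware NMS at IoU 0.7; the confusion matrix uses
confidence 0.25 and class-agnostic greedy IoU matching at 0.45, with one
extra background row/column (missed truths go to the background row,
unmatched detections to the background column; columns with support are
normalized to sum to 1).  Summary precision/recall are reported at the
confidence that maximizes the macro-averaged F1 over the confidence sweep.
These thresholds are the conventions detector frameworks use; published
tables rarely state them, so they are documented here rather than
attributed.

## Synthetic scenes

The generator emulates the challenge regimes of camera-trap data: objects
are procedural textured ellipses with a deterministic per-class signature
(golden-ratio-spaced hue, aspect, stripe/spot texture), placed by
rejection sampling over a cluttered background; occluded pairs are forced
to overlap with IoU ≥ 0.3 and drawn in deterministic z-order with both
boxes fully labelled; illumination in [0, 1] scales brightness and
desaturates toward the gray look of infrared night frames; additive
Gaussian pixel noise completes the render.  Boxes tightly bound each
sprite's ellipse.  Identical spec + seed give bit-identical images and
labels; an infeasible spec raises instead of silently under-generating.

What the generator does **not** model: animal morphology and pose,
perspective and scale continuity, motion blur, compression artifacts, or
class-imbalanced long tails.  Passing tests on these scenes therefore
demonstrate that the pipeline's mechanics (assignment, losses, decoding,
metrics, the stride-4 pathway) work as specified — not that the detector
reaches field accuracy on real imagery.

The small-object benchmark pairs a set whose objects are all 8–24 px (the
ultra-small regime; the 32 px cutoff is an absolute scale set by the
stride ladder, so it is not rescaled with image size) with a mixed set
spanning 16 px up to large.

## Scaled-down test conditions

The behavioral suites run at sizes chosen for a single CPU: 96-px inputs,
3 classes, 8–15 images, ≤ 300 epochs.  The overfit check trains the
enhanced variant on 8 scenes and requires training-set mAP50 ≥ 0.8 within
300 epochs; the ablation check trains both variants identically on the
small-object benchmark for 200 epochs at two seeds and requires the
four-scale variant's test mAP50 to be at least the baseline's.  At 96-px
input the stride-8 grid is 12×12, so 8–24 px objects occupy one to three
cells — the same relative regime that motivates the stride-4 branch at
640.

## Numerical choices and degenerate inputs

Softmax rows are stabilized by max subtraction (an identity); sigmoids use
the tanh form `0.5(1+tanh(x/2))` to avoid overflow; BCE-with-logits uses
the `max(x,0) − xt + log1p(exp(−|x|))` form.  The fusion normalizer's ε
keeps the all-zero weight vector well-defined (output all zeros).  IoU of
disjoint boxes is 0; boxes must have positive area, and degenerate ground
truths are rejected at annotation validation.  Classes without ground
truths are excluded from mAP averages (NaN per-class AP); an evaluation
with no supported class is an error.  Empty label files are valid negative
images.  Dataset splitting floors the validation and test sizes and gives
the remainder to training — the only rounding that reproduces
(4906, 1634, 1634) from 8174 at 6:2:2.

## Known limitations

* CPU-scale only: no GPU path, no mixed precision, no multi-process data
  loading; published-scale accuracy figures on real wildlife datasets are
  out of reach and out of scope.
* The enhanced variant's exact parameter total depends on head-width and
  attention choices the reference table does not pin down; this
  implementation reports its own count (3,204,998 at nc = 10) rather than
  asserting equality with the published 3,205,767 — the published GFLOPs
  (12.5) is reproduced exactly.
* The keyframe sampler's "significant posture change" trigger is
  operationalized as mean absolute grayscale difference with a rate clamp
  (defaults: threshold 15/255, 0.2–3 captures/s); the original criterion
  is qualitative, so this statistic is an artifact decision of this
  package.
* VOC boxes are interpreted as 1-based inclusive pixels (the LabelImg
  dialect) and converted to 0-based half-open before normalization.
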