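# Methods

`mgayolo` implements a family of lightweight one-stage detectors for
apple-leaf disease — the ablation ladder running from a plain small
YOLOv5-style baseline to the final four-head Ghost/C3MB/CBAM/GELU model
("MGA-YOLO") — together with the surrounding machinery: profiling,
evaluation, annotation I/O, augmentation, desk-scale training and a
synthetic scene generator.  Everything runs on a self-contained numpy
tensor/autodiff core (`mgayolo.nn`); no deep-learning framework is
required.

## Architecture

All variants share the anchor-based one-stage layout: a CSPDarknet-style
backbone (Focus stem, stride-2 downsampling convolutions, CSP "C3"
stages, SPP), a PANet neck (top-down then bottom-up fusion), and one
1×1 prediction convolution per scale emitting `3·(nc+5)` channels
(three anchors × box `x,y,w,h` + objectness + class scores; 27 channels
for the four leaf classes).  Channel widths are scaled by
`width_multiple` (rounded up to multiples of 8) and stage repeats by
`depth_multiple`; the bundled configs use the small-model scaling
0.50/0.33.

The bespoke blocks:

* **GhostConv** — the Ghost module: an ordinary convolution produces
  half the output channels (*intrinsic* maps) and a 5×5 depthwise
  convolution derives the other half (*ghost* maps); both halves carry
  batch norm + activation and are concatenated.  For an output of `n`
  channels with `s = 2` this costs roughly `1/s` of the dense
  convolution's multiply–accumulates; the package asserts the ratio is
  within 15% of 1/2 for ≥64 channels.
* **GhostBottleneck / C3Ghost** — residual block
  `GhostConv(c→c/2) → linear 3×3 depthwise (BN, no activation) →
  GhostConv(c/2→c, linear)` with an identity shortcut, and the C3-form
  CSP stage built from it.  The stride-1 depthwise stage is part of this
  package's bottleneck; the upstream ghost-net variant inserts it only
  when downsampling.  This convention (and each one below) was fixed by
  calibrating total parameter counts against the published ablation
  table, which pins them exactly.
* **CBAM** — channel attention (global max + average pooling through a
  shared biased bottleneck MLP, reduction 16) followed by spatial
  attention (channelwise max + mean maps through a 3×3 convolution),
  each a multiplicative sigmoid gate.  The 3×3 spatial kernel (rather
  than the 7×7 of the original CBAM publication) is what the published
  parameter counts require.
* **MBConvA / C3MB** — inverted residual bottleneck: 1×1 expansion
  (ratio 6) with activation, 3×3 depthwise with batch norm but no
  activation, an attention module (CBAM by default; SE with reduction 4
  or coordinate attention with reduction 32 for the ablations) on the
  expanded maps, then a linear 1×1 projection; identity shortcut when
  shapes allow.  C3MB is the CSP stage with MBConvA inner blocks; it
  replaces the CSP stage that follows SPP and the four PANet stages.
* **P6 head** — the four-head model appends a single stride-2 ghost
  module after the P5 output (512→512 channels at width 0.5, 3×3
  primary kernel) and a fourth detection convolution, giving strides
  8/16/32/64 without deepening PANet.  A 1×1 primary kernel cannot
  reproduce the published parameter total; 3×3 reproduces it exactly.
* **Activations** — Swish-1/SiLU `x·σ(x)` by default; the final variant
  substitutes exact GELU `x·Φ(x)` everywhere.  The swap changes neither
  parameters nor FLOPs, which the tests assert.

## Profiling conventions

`count_parameters` sums every trainable element: convolution weights
and biases plus batch-norm affine pairs (running statistics and anchor
grids are buffers, not parameters).  `estimate_flops` counts
convolution multiply–accumulates by the product
`h'·w'·k·k·(c/groups)·n` and adds two MAC-equivalents per batch-norm
element (the affine rescale and shift); pooling and activations are
excluded; GFLOPs = 2·MACs/1e9 for one 640×640 forward pass.  This is
the convention of the profilers customarily used to report such
figures, and it reproduces all published one-decimal values.  Per-module
MACs are exact polynomials of degree ≤2 in the input side (quadratic
for spatial convolutions, linear for coordinate attention's 1-D
encodings, constant for convolutions on globally pooled maps), so the
profiler measures three small probe sizes and evaluates the fitted
polynomial at the target size — identical to a full-size profile at a
fraction of the cost.

## Evaluation

`evaluate` follows the COCO-style protocol: per class, detections are
sorted by confidence and matched greedily to unmatched ground truths at
each IoU threshold (0.50:0.95:0.05), each detection claiming the
highest-IoU available ground truth.  AP is 101-point interpolated
precision (right-continuous envelope, zero beyond the achieved recall);
AP50 is the 0.5 member and mAP the ten-threshold mean.  Reported
per-class precision/recall are taken at the confidence maximising F1 on
the IoU-0.5 curve.  Classes without labels are NaN and excluded from
aggregates; a class with labels but no detections scores 0.  The matcher
is exercised against an exhaustive enumeration oracle on ≤4-box
instances.  Note the greedy confidence-priority matching is *not*
maximum-cardinality matching; adversarial overlaps where they differ
exist even with three boxes.

NMS is greedy per class (keep highest confidence, drop same-class boxes
with IoU above the threshold); ties are broken by coordinates so the
result is independent of input order.  Defaults: confidence 0.25 / NMS
IoU 0.45 for detection, 0.001 / 0.6 for mAP evaluation.

## Training

SGD with momentum 0.937; weight decay 5e-4 applied to convolution
weights only.  The learning rate follows the one-cycle cosine form
`lf(x) = ((1−cos(πx/epochs))/2)(lrf−1)+1`, `lr = lr0·lf`, so training
runs from `lr0` (default 0.01) to `lr0·lrf` (default factor 0.2), with
a linear warmup over the first epochs.  The loss is the standard
composite: CIoU box regression, BCE objectness with per-level balance
weights ([4, 1, 0.4] for three levels, [4, 1, 0.25, 0.06] for four) and
an objectness target interpolating between 1 and the predicted IoU
(`obj_iou_ratio`), and BCE classification.  Targets use multi-anchor
assignment: an anchor matches when both box/anchor side ratios lie
within `anchor_t = 4`, and each match is replicated into the two
nearest neighbour cells.  Gains follow the familiar scaling (box 0.05,
obj scaled by `(img/640)²`, cls by `nc/80`, all by `3/levels`).

Two helpers matter for short desk-scale runs: detection biases are
re-initialised for the actual training resolution (an objectness prior
of ~8 objects per image at each grid), and batch-norm running statistics
are recalibrated to the average batch statistics before evaluation —
the exponential running average (momentum 0.03) has not converged after
a few hundred steps.  `kmeans_anchors` estimates anchors from training
box sizes by Lloyd's algorithm under a shape-affinity distance, sorted
by area across levels.

## The numpy network core

`mgayolo.nn` is a small tape-based reverse-mode autodiff engine over
float32 numpy arrays: elementwise arithmetic with broadcasting,
reductions, the sigmoid/exp/log/erf/softplus/arctan family (with fused
SiLU/GELU), slicing, concatenation, grouped 2-D convolution (im2col +
BLAS for dense, direct kernel-offset accumulation for depthwise), batch
norm, max pooling and nearest-neighbour upsampling.  Gradients of every
primitive are verified against central finite differences in the test
suite.  Max pooling routes gradient to all window elements equal to the
maximum (a measure-zero tie event).  After `backward()` the tape's
reference cycles are broken so graphs are freed by reference counting.
Training throughput is roughly 0.7 s per batch of eight 128×128 images
for the width-0.25 four-head model on one CPU core.

## Synthetic scenes

The generator renders elliptical leaves on a low-frequency gray/straw
background with optional clutter blobs, one tight box and class label
per leaf.  Phenotypes follow the field descriptions in stylised form:
rust = saturated orange spots, scab = olive blotches strung along the
mid-vein, black rot = concentric purple-margined "frog-eye" rings,
healthy = unmarked blade; diseased blades additionally carry a global
tint toward their lesion colour, so the four classes are separable by
mean box colour (a property the tests assert with a nearest-centroid
check).  Leaf placement rejects candidates whose box is covered more
than 50% by earlier leaves, shrinking the size range over retries so
crowded scenes still place.  `generate_dataset` assigns classes
round-robin from a shuffled pool (per-class label counts balanced
within ~10%) and writes images, annotations in any of the three
formats, and train/val/test manifests at a 0.54/0.23/0.23 split.

What the generator does *not* model: real leaf texture and venation,
lighting and shadow, occlusion by other plant organs, the label noise of
hand annotation, and lesion co-occurrence.  Passing the desk-scale
training property therefore demonstrates that the architecture, loss,
assignment, optimiser, decoding and evaluation are wired correctly —
not that the model reaches any particular accuracy on orchard imagery.

## Desk-scale problem sizes

The test suite trains a width-0.25 four-head model at 128 px (the
smallest side compatible with the stride-64 head) on 64 single-leaf
scenes with lightly cluttered backgrounds and horizontal-flip
augmentation, with anchors estimated from the training labels,
`lr0 = 0.1` decaying to `lrf = 0.05`, no weight decay, class gain 2 and
`obj_iou_ratio = 0.5`; it must exceed mAP@0.5 = 0.9 on 32 held-out
scenes within 100 epochs (it typically clears the bar near epoch 55,
about five minutes on one CPU core).  The raised learning rate and
class gain compensate for the small step count of a desk-scale run; at
the published scale (thousands of SGD steps) the standard defaults
apply.  Full-scale training on real imagery is out of
scope: the published accuracy table requires the original dataset and
GPU-scale budgets.

## Known limitations

* Inference and training run at numpy speed: fine for the bundled
  desk-scale checks, far from real-time.
* `Upsample` supports the 2× nearest mode the architectures use.
* Letterboxing assumes square targets; rectangular inference is not
  implemented.
* The confusion matrix uses class-aware greedy matching at a single
  IoU; it is a diagnostic, not part of mAP.
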