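# Methods

## Problem setting

Individual identification of dairy cows from side-view photographs is a
closed-set classification problem: a fixed herd of N known individuals, each
distinguishable by the persistent pattern of dark spots on its body, must be
recognized in images taken against cluttered farm backgrounds under varying
lighting and pose. The constraint that shapes the architecture is
deployment: the model must be small enough (a few MB of weights) to run on
edge devices at a feeding gate, so parameter budget is treated as a
first-class design quantity, audited exactly rather than approximately.

## Architecture

The network is a deliberately shallow pyramid:

```
input (3×H×W)
 └─ stem: 11×11 conv, stride 4, pad 2 → BN → ReLU   (72 channels)
     └─ 3×3 max-pool, stride 2
 └─ multi-scale stage 1: four parallel convs (7×7, 5×5, 3×3, 1×1),
    each conv→BN→ReLU, depth-concatenated              (4×32 = 128 ch)
 └─ SE attention (reduction 16)
 └─ BasicBlock: two 3×3 conv+BN with identity shortcut  (128 ch)
 └─ SE attention → 3×3 max-pool, stride 2
 └─ multi-scale stage 2: widths 104/112/114/114         (444 ch)
 └─ SE attention → 3×3 max-pool, stride 2
 └─ global average pooling → FC → N logits (softmax at inference)
```

The large stem kernel shrinks the feature map quickly (input resolution is
high relative to network depth); the parallel kernels extract spot features
at several scales at once and are merged by channel concatenation, so the
stage's output width is the sum of the branch widths; squeeze-and-excitation
(SE) blocks re-weight channels (global average pool → two-layer FC
bottleneck → sigmoid gates in (0,1)); the residual block lets gradients and
low-level pattern detail bypass the attention-weighted middle of the
network without changing the channel count; and the head is a single FC
layer on globally pooled features instead of a multi-layer FC stack, which
is where most of the parameter savings over an AlexNet-style skeleton come
from.

Conv layers carry no bias anywhere a BatchNorm follows (the BN shift
absorbs it); both SE bottleneck FC layers and the classifier carry biases.

## Exact parameter accounting

Every layer family has a closed-form trainable-element count (conv:
k²·C_in·C_out + 2·C_out for BN; SE with bottleneck b = max(1, ⌊C/r⌋):
2·C·b + b + C; BasicBlock: 2·(9C² + 2C); head: C·N + N). These formulas are
one route; enumerating the constructed weight arrays is the second,
independent route; the test suite holds the two equal on dozens of randomly
sampled configurations. Model size in MB uses 4 bytes per parameter and
2²⁰ bytes per MB, rounded half-up to two decimals — the only convention
consistent with published (count, MB) pairs such as 1,707,592 → 6.51 and
58,314,120 → 222.45.

## Width calibration

Published budgets state a total parameter count but not the per-stage
channel widths. The default configuration is therefore produced once by a
deterministic search (`calibrate_width_config`) for widths whose exact
total equals the budget 1,707,592: a coarse pass over the stem width
(32–96) and equal first-stage branch widths (8–128) on a multiple-of-8
grid, with the second stage's 7×7/5×5 widths on the same grid and its
3×3/1×1 widths solved at unit granularity from an integer divisibility
condition. Two preferences narrow the 100+ exact solutions: stage widths
may not shrink along the network (stem ≤ C1 ≤ C2, the usual classification
pyramid — without this the budget is swallowed by a very wide middle block
feeding a narrow head), and among the rest the most balanced second-stage
branch widths win, with remaining ties preferring reduction ratio 16, a
stem near 64 and a second stage near twice the first. The winner (stem 72,
first stage 4×32, second stage 104/112/114/114, r=16) is committed to
`src/spotid/resources/default_config.yaml` and loaded, never re-searched,
at run time.

The SE reduction ratio defaults to 16 (the standard choice for this block
family); the search may also consider 8 and 4. The downsample schedule
(stem stride 4 plus three 3×3/stride-2 max-pools) is config-driven;
pools use padding 1 so small inputs degrade gracefully. Which stages carry
pooling is an open choice; placing pools after the stem and after the
second and third attention blocks keeps the two multi-scale stages at
different resolutions while leaving a usable map for global pooling.

## Numerical engine

The network runs on a compact numpy engine written for this package:
im2col convolution lowered to BLAS matrix products, hand-derived backward
passes for every layer (validated against double-precision finite
differences), BatchNorm with running statistics (momentum 0.1, eps 1e-5;
batch statistics in training, running statistics at evaluation), SGD with
classical momentum, and Glorot-normal initialization (variance
2/(fan_in+fan_out), zero biases, unit BN scales) drawn in a fixed stage
order so a seed fully determines the weights. All tensors are float32 in
NCHW layout.

## Synthetic herd

No public dataset accompanies the identification task this package
implements, so the generator produces one procedurally. Each individual is
a seeded set of 4–20 irregular dark blobs (wobbly ellipses with a
cosine-modulated boundary radius) placed on the torso of a fixed side-view
silhouette; the blob set is a pure function of (base seed, identity label).
Rendering composites the body over either a cluttered scene (low-frequency
color texture plus fence-like bars) or a uniform "simple" backdrop, then
applies pose jitter (scale/shear/translation), occluding rectangles,
a global brightness factor and Gaussian sensor noise. Each nuisance draws
from its own seeded stream, which gives two useful guarantees: generation
is byte-reproducible, and switching the background mode changes no body
pixel, so background-sensitivity experiments are exactly controlled.

Defaults: 13 identities (the herd size of the motivating setting),
brightness jitter 0.2, pose jitter 0.08, occlusion ≤5% of the frame, noise
σ=6 grey levels. Default herd seed: 20210601. The generator emulates the
identity-bearing structure of real coat patterns, not their photometric
statistics: no articulation, no perspective, no real camera noise model.
Success on this data shows the pipeline and model learn pattern identity
under controlled nuisance; it does not certify accuracy on real farm
photographs.

## Preprocessing protocol

Images are bilinearly resized to a common square resolution and scaled to
[0,1]; training batches are additionally normalized by the training set's
own per-channel mean/std (computed at training start — deterministic, and
always from training data only). The split is 8:2 per identity (floor on
the training share, remainder to validation, so every individual has
validation images); splitting before augmentation guarantees no validation
image enters training in any rotated form. Augmentation triples the
training set: each image contributes itself plus two copies rotated by
angles drawn without replacement from {90°, 180°, 270°} (lossless
rotations; horizontal flips are available behind a flag but off by
default). Batches of 32 are drawn in a fresh seeded shuffle each epoch;
only the final batch of an epoch may be short.

## Training protocol

Up to 40 epochs of SGD (momentum 0.9, learning rate 0.01 — the protocol's
published learning-rate sentence is incomplete, so the value is this
package's choice, kept in config), cross-entropy loss on logits, softmax
only at inference, Xavier initialization with zero bias. The best
validation weights are checkpointed and restored. An optional
`stop_at_val_accuracy` ends training once validation accuracy reaches a
threshold; the report records how many epochs actually ran.

## Problem sizes used by the test suite

The packaged checks train the full 1.7M-parameter default model on a herd
of 13 identities × 12 images rendered at 96×96 and trained at 56×56
resolution, with early stop at 95% validation accuracy — sizes chosen so
the whole suite runs on a single CPU core in minutes while still exercising
every stage end to end. Under these conditions all five tested seeds reach
≥97% validation accuracy within 8 epochs, and the uniform-background herd
converges faster than the cluttered one, matching the expected direction of
the background effect. Published accuracies on real herds (≈98%) are
properties of private photographs and are not reproduction targets of this
package.

## Heat maps

Recognition visualizations use Grad-CAM on the last attention-weighted
convolutional stage: the target logit's gradient w.r.t. that stage's
activations is spatially averaged into channel weights, the weighted
activation sum is ReLU-rectified, bilinearly upsampled to the input size
and min-max normalized to [0,1] (an all-zero map stays zero).

## Known limitations

- The numpy engine is single-device and unaccelerated; full-resolution
  (224×224) training is possible but slow, so desk-scale runs use reduced
  resolution.
- The synthetic herd's nuisance model is an invention (the real capture
  conditions are not quantitatively characterized anywhere); clutter
  statistics, occlusion geometry and noise levels are plausible, not
  measured.
- Ablation variants share the full model's widths, so their parameter
  totals are internally consistent but not comparable to any published
  intermediate architecture, whose widths are unknown.
- BatchNorm running statistics make evaluation depend mildly on training
  history; two models with identical weights but different BN histories can
  disagree on borderline inputs.
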