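# spotid

Individual identification of dairy cows from side-view coat patterns with a
lightweight convolutional network.

Holstein cows carry individually distinctive black-and-white spot patterns,
which makes closed-set visual identification of a known herd possible
without ear tags or RFID. The catch for on-farm deployment is model size:
the classifier has to run on edge hardware, so this package treats the
parameter budget as an exact, audited quantity rather than a by-product.

The network is a shallow pyramid: an 11×11 stem convolution (stride 4), a
four-branch multi-scale module (parallel 7×7, 5×5, 3×3, 1×1 convolutions
merged by depth concatenation), squeeze-and-excitation (SE) channel
attention, a residual BasicBlock (two 3×3 convolutions with an identity
shortcut, again followed by SE), a second multi-scale+SE stage, and a
global-average-pooling head with a single fully connected classifier. With
the committed default widths the model has exactly **1,707,592** trainable
parameters — **6.51 MB** at 4 bytes/parameter — for 13 output classes.

Because no public imagery accompanies the task, the package ships a
procedural herd generator: each individual is a seeded set of irregular
dark blobs on a fixed side-view silhouette, rendered with controlled
nuisance (clutter or uniform background, pose jitter, occlusion, lighting,
noise), so the whole pipeline — generation, 8:2 stratified split, rotation
tripling, SGD training, evaluation, ablations, Grad-CAM heat maps — runs
end to end with no downloads. Everything runs on a compact numpy engine
(im2col convolutions with hand-derived, finite-difference-validated
backward passes) included in the package.

## Worked example

Audit the default architecture:

```
$ spotid count-params
stem.conv.W              26,136
stem.bn.gamma                72
stem.bn.beta                 72
ms1.b7x7.conv.W         112,896
...
fc.b                         13
-------------------------------
total                 1,707,592
size (MB)                  6.51
```

Every trainable array is listed (conv weights, BatchNorm scale/shift, SE
bottleneck weights/biases, classifier); the total is the exact budget the
default widths were calibrated to, and the MB figure is that count at 4
bytes per parameter.

Generate a herd, prepare it, and train (desk-scale sizes shown):

```
$ spotid generate-data --n-identities 13 --per-identity 12 --image-size 96 \
      --seed 20210601 --out-dir herd/
wrote 156 images under herd/
$ spotid prepare-data --data-dir herd/ --seed 1
train 351 (incl. rotations), val 39
$ spotid train --data-dir herd/ --image-size 56 --epochs 8 --seed 1
epoch   1  train loss 2.5849 acc 0.1510  val loss 2.5097 acc 0.0769
epoch   2  train loss 1.8034 acc 0.4160  val loss 3.2024 acc 0.1538
epoch   3  train loss 1.0011 acc 0.8091  val loss 0.9541 acc 0.8205
...
epoch   8  train loss 0.0116 acc 1.0000  val loss 0.2089 acc 0.9744
best val accuracy 0.9744 (epoch 8); report -> train_report.json
```

The 117 training originals are tripled to 351 by lossless rotations; the
39 validation images (3 per individual) are never augmented. On this small
synthetic herd the 1.7M-parameter model separates all 13 individuals to
97%+ validation accuracy within a handful of epochs; `train_report.json`
holds the full per-epoch curves and the final confusion matrix.

`spotid ablate` trains the module-attribution variants (stem+multi-scale+SE
only; full minus the second multi-scale+SE; full) and tabulates accuracy
against exact parameter counts, and `spotid heatmap` renders a Grad-CAM
overlay showing where the trained model looks — on clean runs, the torso
spots rather than the background.

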