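# Methods

## Architecture

The classifier follows a "downsample – fuse – enhance" design. A
standard 18-layer residual network is truncated after its second stage:
the stem (7×7 conv stride 2, BN, ReLU, 3×3 max-pool stride 2) and the
64- and 128-channel stages are kept, deeper stages discarded. A 1×1
convolution maps the 128-channel output to 256 channels; we follow the
common adapter idiom of 1×1 conv + BN + ReLU (the normalisation and
activation can be disabled via `BackboneConfig.adapter_norm_act`). For a
224×224 input the base feature `F0` is therefore 28×28×256; in general
the output side is the input side divided by 8, which is why inputs must
be multiples of 8 and at least 32 pixels.

Two stride-2 3×3 convolutions (+BN+ReLU) derive `F1` and `F2` with sides
`⌊(s+2−3)/2⌋+1`. Fusion is bottom-up: the deepest map is enhanced by a
Dynamic Swin Window (DSW) stack at its own resolution, bilinearly
upsampled (align-corners off) to the next shallower level, and added
element-wise; the sum is enhanced and propagated once more, and the
result is added to `F0`. An alternative ordering that upsamples first
and runs attention at the shallower resolution is available as
`fusion_order="pre_add"`; it is shape-checked but not the default,
because the forward procedure that defines this architecture enhances
at native resolution before upsampling. With `cross_scale=False` the
additive skip terms are dropped (ablation mode) and only the attention
chain output is classified.

## Dynamic Swin Window blocks

Each DSW stack holds `depth` pre-norm transformer blocks (default 2):
`x ← x + WindowAttention(LN(x))`, then `x ← x + MLP(LN(x))` with a GELU
MLP of expansion 4. The feed-forward sublayer can be removed with
`with_ffn=False`; whether the original design includes one is not
specified, so it is on by default and config-exposed.

**Window size** adapts to the pyramid level: 7 on the level-1 map, 5 on
the level-2 map (strategy `mix`); `fixed5`/`fixed7` force one size
everywhere for ablations. **Shift** alternates by block index `i`:
even blocks use the regular grid, odd blocks roll the map cyclically by
`min(3, ⌊H/2⌋, ⌊W/2⌋)`; a depth of at least 2 is therefore required for
any shifted block to occur.

**Partition.** The map is rolled by (−s, −s), zero-padded bottom/right
to window multiples, and tiled into M×M windows. Two masks apply before
the softmax (additive −1e9): padded positions are never valid keys, and
when s > 0, pairs of positions that were not contiguous on the original
map (they sit on opposite sides of the wrap-around seam introduced by
the roll, per axis) may not attend to each other. A padded query row
falls back to attending other padded positions including itself, so no
softmax row is ever empty and no NaN can arise. The masked computation
is verified against a dense float64 oracle that computes attention
directly on the original map's shifted-window neighbourhoods for every
map up to 8×8.

**Attention** is multi-head (8 heads at 256 channels, d_k = 32) with a
learned relative-position bias table of size (2M−1)² per head, indexed
by in-window offset. The key projection carries no bias: a constant
added to every key shifts all logits of a query row equally and cancels
in the softmax, so such a parameter could never receive gradient.

## Classification and loss

Global average pooling followed by a single linear layer produces
logits; training minimises softmax cross-entropy (the standard choice
for single-label classification — the architecture itself does not
prescribe a loss). AdamW with learning rate 1e-3, weight decay 0.01
(decoupled), batch size 32 and 50 epochs are the defaults; weight decay
is not part of the published protocol and is config-exposed. No
learning-rate schedule is used. Replicate training over five seeds and
mean ± sample SD (n−1; 0 for a single replicate) aggregation mirror the
evaluation protocol. Model selection is best validation macro recall,
config-exposed, since macro recall is the metric the evaluation design
emphasises for imbalanced classes.

## Metrics

All four metrics are computed from the confusion matrix (rows true,
columns predicted): accuracy is the trace over n; MP/MR/MF are
unweighted means of per-class precision, recall and F1. MF is the mean
of per-class F1 scores, *not* the harmonic mean of MP and MR. A class
with an empty denominator (never predicted; no true samples)
contributes 0 to the macro mean rather than being dropped — with a
10-image validation class, dropping it would silently reward a model
that ignores it. PR curves are one-vs-rest on softmax scores with
thresholds at the distinct score values and area by the rectangle rule.

## Synthetic data generator

The generator emulates a 7-class edible-mushroom collection: per-class
counts default to 1,713 train / 722 validation (2,435 total, a 7:3
split) with the rare "Mix" class at 14/10. Each species renders a
parametric silhouette (cap ellipse over a stipe rectangle) with a
species-specific palette, aspect ratio and procedural texture (gills,
ridges, speckle, cracks, wavy folds), over a cluttered background, with
seeded jitter in position (±6 %), scale (0.88–1.08), hue (±10/255),
illumination gain (0.94–1.06) and pixel noise (σ=4/255). The jitter
ranges were set so that classes remain separable by a multinomial
linear probe on per-image colour mean/SD features (≥90 % validation
accuracy on the default set), which the generator guarantees by
construction via distinct mean palettes — this is what makes downstream
training tests informative. "Mix" samples its renderer uniformly from
the other six species and is therefore irreducibly confusable; it
exists precisely to make macro and micro metrics diverge. Identical
(spec, seed) produce byte-identical PNG trees; class indices are
alphabetical over folder names.

What the generator does **not** model: real photographic variation
(viewpoint, occlusion, specular highlights, inter-species look-alikes,
label noise). Passing the training-sanity and separability tests
demonstrates that the architecture, optimiser and pipeline function
correctly on learnable data of the published shape and imbalance — it
says nothing about accuracy on real mushroom photographs.

## Problem sizes

The NumPy core runs on one CPU; problem sizes in the test suite are
chosen accordingly and stated here as the package's own defaults. The
training-sanity check uses the default class proportions scaled by 1/8
(214 train / 90 validation images at 224×224, minimum 2 train / 1 val
per class) with batch size 4, preserving ≈54 optimiser steps per epoch
— the same as the full protocol's 1713 images at batch 32 — so the
optimisation schedule, not just the data distribution, matches the
study conditions; 5 epochs, seed 0 reach 98.9 % validation accuracy in
about 5 minutes. The
overfit-sanity check drives loss below 0.1 on one repeated 64×64 batch.
Oracle comparisons run in float64 against float32 implementations with
tolerance 1e-6.

## Numerical choices

- float32 parameters and activations throughout; accumulations in BLAS.
- Attention masking uses an additive −1e9 (safe under float32 softmax
  with max-subtraction) rather than literal −inf, avoiding NaN from
  (−inf) − (−inf).
- Bilinear interpolation is implemented as two precomputed row-stochastic
  interpolation matrices (align-corners off); upsampling to the input
  size is exactly the identity.
- He-normal initialisation for convolutions, truncated normal (σ=0.02,
  clipped at 2σ) for linear layers and the bias table, zeros for all
  biases; every weight draw comes from a generator seeded by the model
  seed, so a (config, seed) pair fully determines the network.
- Max-pool ties resolve to the first maximal element (argmax order), as
  is conventional.
- Batch-norm uses batch statistics in training and running statistics
  (momentum 0.1) in evaluation; running statistics live in checkpoints
  but are not counted as trainable parameters.

## Known limitations

- Pretrained backbone weights are supported only via a user-supplied
  weight file; the default is seeded random initialisation, so headline
  accuracies from transfer learning are out of scope.
- The full 29M-parameter configuration of the published table is not
  reproduced; the assembled default model has ≈5.1M trainable
  parameters and the architecture satisfies the stated <30M budget.
  Which additional width/depth choices would reach 29M is not derivable
  from the published description.
- Single-label classification only; the default pipeline resizes and
  rescales without augmentation (an optional random horizontal flip can
  be enabled with `TrainConfig.hflip`); no GPU path.
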