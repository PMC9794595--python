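# Methods

## Problem setting

Organoids — self-organised 3-D cultures grown here from bladder-cancer
cells in Matrigel — are imaged in brightfield over a culture week (days 1,
3, 5, 7), with and without drug treatment. Growth is quantified by
segmenting every organoid in each image and tracking the distribution of
per-organoid areas per group and day. The images are hard to segment:
illumination is uneven, organoid boundaries are blurred, neighbouring
organoids adhere, and the background is littered with out-of-focus
"ghost" organoids and bubbles that must not be counted as foreground.

The package implements the complete pipeline: scene synthesis with exact
ground truth, preprocessing and annotation I/O, an attention U-Net variant
with dynamic convolutions, class-weighted training, five-metric
evaluation, and the group-level growth statistics.

## Segmentation model

The network is an encoder–decoder with skip connections (depth `d`
downsamplings, channel width doubling from `base_channels`). Four
ingredients distinguish it from a vanilla U-Net.

**Res-double dynamic convolution.** Each double-conv block is
`BN → ReLU → DyConv(dilation 1) → BN → ReLU → DyConv(dilation 2) → BN`,
added to a residual projection (identity, or 1×1 conv when the channel
count changes) and passed through a final ReLU. A dynamic convolution
holds K parallel kernels {W̃_k, b̃_k}; a squeeze-style MLP maps the
globally pooled input to K logits and a temperature-scaled softmax yields
attention weights π_k(x) with 0 ≤ π_k ≤ 1 and Σ_k π_k = 1. The applied
kernel is the convex combination W̃(x) = Σ_k π_k(x) W̃_k (and likewise the
bias), so the effective filter adapts per input while the cost stays close
to one convolution. By linearity, convolving with the aggregated kernel
equals the π-weighted sum of the K individual convolutions — the oracle
used in the tests. The ordering of BN/ReLU/conv inside the block is one of
several defensible readings of the block diagram; it is fixed in one place
(`ResDoubleDyConv`) and documented here.

**Learned downsampling.** Max pooling is replaced by a 5×5, stride-2,
padding-2 convolution (output ⌈H/2⌉×⌈W/2⌉) that also doubles the channel
count, followed by BN + ReLU.

**Coordinate attention (CA)** on the last two encoder levels (the level
before the bottleneck, and the bottleneck). With input x of size C×H×W:

    z_c^h(h) = (1/W) Σ_i x_c(h, i),      z_c^w(w) = (1/H) Σ_j x_c(j, w),
    f = ReLU(F1([z^h, z^w])),            (shared 1×1 conv, C → max(C/r, 1))
    g^h = σ(F_h f^h),  g^w = σ(F_w f^w), (per-direction 1×1 convs, back to C)
    y_c(i, j) = x_c(i, j) · g_c^h(i) · g_c^w(j).

Both pooled descriptors are normalised by the length of the axis they
average over (z^w by the height H), the standard coordinate-attention
definition. Since g^h, g^w ∈ (0,1), CA is a bounded elementwise modulation.

**Attention gates (AG)** on every skip connection and **decoder fusion**
at the head. The gate computes α = σ(ψ(ReLU(W_x x^l + W_g g))) at the
gating signal's resolution (x^l is brought down by a stride-2 1×1 conv),
bilinearly restores α to x^l's size, and outputs α ⊙ x^l; zeroed
transforms give exactly α = σ(0) = 0.5. The decoder head convolves every
decoder level to `base_channels` maps, upsamples all to the finest
resolution, concatenates and reduces with a 1×1 convolution before the
sigmoid output head.

Ablation variants remove exactly one ingredient: `rdau_wA` both attention
modules (CA and AG), `rdau_wD` the res-double dynamic blocks (plain double
convolution instead), `rdau_wC` the decoder fusion (head on the finest
decoder level only). `unet` is the classic max-pool/double-conv/plain-skip
baseline.

### Numerical core

No GPU framework is used: the network runs on a small reverse-mode
autodiff engine over NumPy (`rdaunet._tensor`). Convolution is im2col +
BLAS matmul with strided/dilated support and per-sample kernels for the
dynamic convolution; upsampling is an exact factor-2 bilinear operator
with a hand-derived adjoint; the stride-2 transposed convolution uses a
2×2 kernel (exact spatial doubling). All structured operators are verified
against central finite differences or adjoint identities in float64; the
network itself runs in float32 (scalar operands are coerced so nothing
silently upcasts). Everything is plain vectorised NumPy, hence
deterministic given a seed; the only platform caveat is the usual
floating-point variation across BLAS builds, which does not affect any
test at its stated tolerance.

## Training

Loss: weighted binary cross-entropy,
`WBCE = −mean[β·p·log p̂ + (1−p)·log(1−p̂)]`, with predictions clamped to
[1e-7, 1−1e-7]. β < 1 down-weights the foreground term, which penalises
false positives relatively more and trades a little recall for precision —
the desired direction when ghosts and bubbles would otherwise be
segmented. Defaults: β = 0.7, Adam at a constant learning rate 1e-3, up to
80 epochs, batch size 4, early selection by validation loss with the best
checkpoint restored (last epoch if no validation set; a NaN loss aborts
with a diagnostic). The dynamic-conv softmax temperature anneals linearly
from 30 to 1 over the first 10 epochs so early training sees near-uniform
kernel mixtures. One integer seed drives weight init, shuffling and data
generation; two runs with the same seed produce identical loss curves.

The 80-iteration training budget is counted in epochs; `max_steps` caps
optimiser steps directly for the desk-scale experiments.

## Synthetic scenes

The generator renders the named confounders with exact ground truth:
elliptical organoids (equivalent radius ~ N(mean, sd) clipped at 2 px,
eccentricity uniform in a configurable range, uniform orientation) with a
bright interior (+0.18 over a 0.55 background) and dark rim (−0.22 on
normalised radius 0.75–1), Gaussian boundary blur, a low-order polynomial
illumination field with configurable peak-to-trough relative amplitude,
additive Gaussian noise, low-contrast heavily blurred ghost rings and thin
high-contrast bubble rings. Ghosts and bubbles appear in the image but
never in the mask. With probability `adhesion_prob` a new organoid is
placed touching an existing one; overlapping ellipses stay separate
catalogue entries but merge in the mask, and pixels claimed by an earlier
organoid are not re-counted, so catalogued areas always sum to the mask's
foreground count. Masks come from an exact point-in-ellipse test on pixel
centres (row-major, origin top-left, integer centres). Placement uses
rejection sampling with a bounded retry budget and fails loudly when the
canvas cannot hold the requested population.

Growth series: expected area multiplies by `growth_rate_per_day` per
culture day (radius by its square root), with days (1, 3, 5, 7), 4 images
per day and 70–160 organoids per 1024×768 image by default — the regime
of a real screening well. Per-scene seeds derive from (series seed, day,
replicate), so two groups with different seeds are independent replicates
of the same protocol.

What the generator does **not** model: texture inside organoids, debris,
focal drift, non-elliptical shapes, and optically realistic point-spread.
Passing tests therefore demonstrate that the pipeline recovers known
geometry and known group effects under the named confounders — not
clinical-grade performance on real micrographs.

## Evaluation and screening

Metrics come from pixel confusion counts (Acc, precision, recall, IoU,
DSC); pooled counts satisfy DSC = 2·IoU/(1+IoU) exactly, and both pooled
and per-image-mean aggregations are computed and labelled because
published tables do not always state which was used (per-image averaging
can even produce DSC < IoU). 0/0 ratios (image empty in both prediction
and truth) are reported as 1.0 and flagged. The comparison report
subtracts a reference variant's row from every other row in percentage
points; fed the published eight-model indicator table it reproduces all of
that table's printed pairwise gains.

Screening decomposes masks into 8-connected components (adhering organoids
merge, as a 2-D segmentation genuinely sees them; 4-connectivity is a
flag), drops components under 30 px as speckle, pools per-organoid areas
per (group, day), draws quartile-annotated violins whose summary CSV
carries exactly the plotted statistics, and compares control vs treatment
per day with a two-sided Welch t-test (Student optional) at the organoid
level. No multiple-testing correction is applied by default (two planned
comparisons per day); Bonferroni-style adjustment is a caller-side option.

## Problem sizes and defaults chosen for the bundled experiments

- Overfit check: 8 scenes of 128×128 with 10 organoids, 3 ghosts, 2
  bubbles; model base 8 channels, depth 3, K = 4; 120 Adam steps.
- Loss-asymmetry check: 10 harder 64×64 scenes (7 ghosts, 3 bubbles,
  noise 0.06, blur 1.5, illumination 0.25), 6 train / 4 validation, 120
  steps, β = 0.3 vs 1.0 from identical init and batch order. The heavy
  clutter keeps both runs away from the clean-data ceiling so the
  precision/recall trade-off direction is decided by the loss, not by
  run-to-run noise.
- Screen: two groups, growth 1.35×/day (control) vs 1.10×/day (drug),
  days 1 and 7, 4 images/day, 70–160 organoids per image.

## Known limitations

- The engine is CPU-only and desk-scale; full-resolution micrographs
  (1944×2592) should be processed with the tiling helpers
  (`imaging_io.pad_to_multiple` / `tile_image` / `stitch_tiles`,
  default 512×512 tiles with 64 px overlap, centre-priority stitching).
- Encoder widths, K, the CA reduction ratio and β are free parameters;
  defaults (base 32, K = 4, r = 16, β = 0.7) follow common practice for
  these building blocks and are all configurable.
- Whether CA sits before or after the residual addition is unspecified;
  it is applied to the block output (after the final ReLU).
- Adhering organoids are one connected component at screening time;
  separating them would need instance segmentation or 3-D imaging, which
  is out of scope.
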