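# Methods

This note records the model as implemented, the parameters that matter, the
numerical choices made where the design was open, what the synthetic data do
and do not emulate, and the known limitations.

## Model

### Feature extraction

Each modality has three independent extraction branches (an option shares
them across modalities). A branch is two stride-1 convolutions (scale 0)
followed by four pairs of (stride-2 downsampling block, stride-1 block), so
exactly four spatial halvings produce the five-scale pyramid F₀..F₄. Input
sizes must be divisible by 16 and at least 48 pixels so the coarsest scale
stays ≥ 3×3 (the Sobel stencil's minimum support).

A feature-extraction block computes

    out = LeakyReLU( plain(x) + s1 + s2 ),
    s1  = Conv(S(x)),          s2 = Conv(S(s1)) + s1,

where S is the depthwise Sobel gradient magnitude |Δx∗f| + |Δy∗f| with
reflective padding. The magnitude is the sum of the two absolute directional
responses (the operational expansion of the gradient-magnitude definition);
the same operator is reused by the texture loss for internal consistency.
The two gradient stages have independent convolution weights; the skip
connection on the second stage keeps gradients bounded. Downsampling is a
stride-2 3×3 convolution inside the first block of each pair; no other
operation changes spatial size. Default channel widths per scale are
(16, 32, 64, 128, 256), configurable through `extract.channels`; widths must
be non-decreasing with depth. No batch normalization is used in the
extractor; LeakyReLU slope is 0.01.

### Attention fusion and reconstruction

Five fusion blocks run coarse-to-fine; block i consumes the scale-i features
of all six pyramids (3 branches × 2 modalities) plus the upsampled output of
block i+1 (the coarsest block has neither a predecessor nor any cross-scale
processing). All masks are sigmoid outputs, and every modulation has the
form F · (1 + M₁ + M₂), so multipliers lie strictly in (1, 3).

- **Cross-modal:** input features are batch-normalized ("normalization" is
  not named by the design, BN chosen for symmetry with the rest of the
  network); each modality's mask is M = σ(Conv(ReLU(Conv(·)))) computed from
  its own normalized features, and the cross mask for modality a is exactly
  modality b's own mask. Attended features are concatenated and reduced
  2C→C by a pointwise convolution (`fusion.reduction_kernel`, default 1).
- **Cross-branch:** the three branch outputs are concatenated channel-wise
  (joint rather than pairwise fusion; the alternative reading of the block
  diagram), globally max- and average-pooled to channel descriptors, passed
  through one shared two-conv bottleneck (reduction 4), and the result is
  BN(Conv(F·(1+M_max+M_avg))) with a 3C→C reduction.
- **Cross-scale:** coordinate attention. The previous block's output is
  bilinearly upsampled ×2 and passed through three Conv-BN-LeakyReLU layers
  that interpolate its channel count down to the current scale's; current
  and previous features are concatenated, row/column average-pooled, sent
  through a shared Conv-BN-hswish bottleneck and per-direction
  convolutions/sigmoids (hswish applied after the shared convolution,
  following the coordinate-attention ancestry), and reduced 2C→C.

Reconstruction is three 3×3 convolutions (BN + LeakyReLU on the first two)
and a terminal sigmoid guaranteeing output in [0,1].

### Losses

Total = content + similarity + semantic.

- Intensity: mean L1 distance between I_f and max(I_ct, I_mri). The
  1/(HW)·‖·‖₁ formulation is read as sum-then-divide, i.e. a pixel mean;
  batches are averaged arithmetically.
- Texture: mean L1 distance between Sobel magnitudes, same reading.
- Content = intensity + α·texture with α = 5 (config `loss.alpha`).
- Similarity: 1 − mean of the two SSIM values. SSIM uses the standard
  11×11 Gaussian window, σ = 1.5, valid-window averaging, L = 1 for [0,1]
  images, c₁ = (0.01L)², c₂ = (0.03L)². The window shrinks to the nearest
  odd size on images smaller than 11 pixels.
- Semantic: see below.

### Unsupervised segmentation and the semantic loss

A small encoder–decoder (two stride-2 stages, bilinear ×4 decoding, 1×1
head, feature dimension D = 32 by default, `semantic.feature_dim`) maps an
image to unit-norm per-pixel features. For each fused image two views are
built by brightness/contrast/gamma jitter (bounds ±0.1 / ±10% / ±20%,
`semantic.jitter_*`); the second view is horizontally flipped with
probability ½ and its feature field inverse-aligned after encoding (an
integer-factor nearest-neighbour rescale is available in the transform API
but off by default, keeping the round trip exact). Pixels of each view are
pooled over the batch and clustered independently by k-means (K = 8 default,
`semantic.K`; Lloyd iterations with k-means++ seeding, 10 iterations, empty
clusters re-seeded from the farthest point, centers re-normalized to unit
length). The per-pixel loss is the soft-assignment negative log-likelihood
under cosine distance; the within-view term pairs each view with its own
labels/centers, the cross-view term with the other view's, and
L_semantic = L_within + L_cross, averaged per pixel. Pseudo-labels and
centers are numpy constants within a step (stop-gradient): gradients reach
the weights only through the features. Clustering is re-run on every
semantic-loss evaluation over the pooled batch — the direct reading of the
clustering objective applied at batch level; per-image clustering and rarer
refreshes are the obvious variations and were not pursued.

### Alternating training

Schedule: cycles × (fusion phase, segmentation phase); defaults 5 cycles of
(20, 10) epochs. Fusion phases minimize the full loss with the segmentation
network frozen (its incidentally computed gradients are discarded);
segmentation phases fuse with the frozen fusion network under `no_grad` and
minimize L_semantic alone. Only one network's parameters change in any
epoch, asserted by state hashing in the tests. Optimizer is Adam
(lr 1e-4 default, β = (0.9, 0.999)), batch size 4, no scheduler; the
segmentation network is never pretrained, and the semantic term enters
fusion training from the first cycle. One RNG seeded by `training.seed`
drives weight initialization, batch order, jitter draws and k-means seeding,
making runs bit-reproducible. Checkpoints are written as deterministic
uncompressed zip archives (fixed timestamps) with a JSON sidecar echoing the
config, so saving an unchanged state reproduces the file byte for byte.

## Metrics

The evaluation metrics follow their canonical published formulations, since
they are conventionally cited by name in the fusion literature rather than redefined:

- PSNR = 10·log₁₀(L²/MSE), +inf sentinel at zero MSE.
- AG: mean of sqrt((Δh² + Δv²)/2) over forward-difference pixels.
- SF = sqrt(RF² + CF²) from RMS row/column first differences.
- Qabf: Xydeas–Petrović edge preservation — Sobel strength/orientation per
  image, relative strength and orientation agreement mapped through the
  standard sigmoids (Γ_g = 0.9994, k_g = −15, σ_g = 0.5; Γ_α = 0.9879,
  k_α = −22, σ_α = 0.8), weighted by source gradient strength (exponent 1).
- Nabf: Petrović artifact measure — the preservation deficit summed over
  locations whose fused gradient exceeds both source gradients, normalized
  by total source gradient strength.
- VIF: pixel-domain four-scale Gaussian-scale-mixture variant,
  σ_nsq = 2; pyramid scales whose subband is smaller than its window are
  dropped so 32×32 fixtures evaluate.
- MS-SSIM: five-level product with exponents (0.0448, 0.2856, 0.3001,
  0.2363, 0.1333), 2×2 average-pool downsampling; the window shrinks at
  coarse levels so 64×64 images support all five levels; levels=1 reduces
  exactly to SSIM.
- Two-reference metrics are averaged over the two sources (a `max` mode is
  available); flat-input degeneracies of Qabf/Nabf are defined as 0.

Every fast metric and all three attention blocks are checked against scalar
double-loop reference implementations in the test suite.

## Synthetic phantoms

The generator emulates the statistical structure of registered CT/MRI brain
slices: modality A has a bright elliptical ring (intensity 0.9 on
background 0.05, mean > 0.8 before noise) and small hyper-intense foci
(0.95); modality B has correlated interior texture (Gaussian-blurred white
noise rescaled to [0.3, 0.7], correlation length `texture_scale_b`) and
larger bright masses (0.9) placed disjointly from the foci by rejection
sampling. Additive Gaussian noise (sd 0.01 default) is applied per modality
and intensities are clipped to [0,1]. A ground-truth region map
(background/ring/tissue/focus/mass) is emitted although the method itself is
unsupervised — it enables sanity checks of the clustering. Pairs are
deterministic in the spec; datasets derive per-pair seeds seed+i.

What the phantoms do **not** emulate: anatomy, partial-volume effects,
modality-specific noise statistics (Rician MRI noise, CT streaking),
registration error, or 3-D context. Passing tests therefore demonstrate the
correctness and trainability of the pipeline, not clinical fusion quality.

## Problem sizes and presets

The default configuration (256×256 images, channels up to 256, five cycles
of 20+10 epochs) matches the intended application scale. Tests and the
acceptance script use a desk-scale preset chosen once (`RunConfig.tiny`):
channel widths (8, 12, 16, 24, 32), K = 4, D = 16, learning rate 1e-3 —
appropriate for few-step overfit runs on 64×64 phantoms, where the default
1e-4 would barely move the weights in a handful of Adam steps. The
acceptance run trains 8 pairs at 64×64 for one cycle of 3 fusion + 2
segmentation epochs; at that scale the trained model roughly doubles its
mean SSIM-to-sources over initialization while the fusion loss falls
epoch over epoch — the numbers themselves are written by
`scripts/acceptance.py`.

## Numerical choices

- All arrays are float64; the in-package autodiff engine is validated
  against central finite differences (tolerances 1e-5 relative / 1e-6
  absolute on the operator tests, 1e-3 relative for the loss-level checks).
- |·| and max use subgradients (sign(0) = 0; ties split gradient equally).
- Bilinear upsampling uses align-corners-false interpolation matrices,
  making the backward pass the exact transpose.
- BatchNorm uses batch statistics in training and running statistics
  (momentum 0.1) in evaluation; oracle tests run in eval mode with fixed
  stats for determinism.
- The gamma jitter adds 1e-6 before exponentiation to stay differentiable
  at zero, skipped when γ = 1 so the degenerate transform is the identity.
- k-means ties and empty clusters: labels by argmin (first minimum), empty
  clusters re-seeded with the point farthest from its center; the Lloyd
  objective is non-increasing across iterations by construction and
  asserted in tests.

## Limitations

- CPU-only numpy execution: full-scale training (256×256, default widths,
  five cycles) is supported by the code but slow; the package is meant for
  method study and desk-scale experiments, not production training.
- 2-D single-channel slices only; color (PET-like) inputs are fused on the
  luminance channel with optional YCbCr chroma re-attachment; volumetric
  formats are out of scope.
- The segmentation component is a lightweight clustering network designed to
  supply the semantic loss, not a benchmark segmentation model.
- Ablation variants (no semantic loss, no attention masks, single branch,
  single scale) are configuration switches intended for qualitative
  comparison at desk scale.
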