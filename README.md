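# semfuse

Semantic-aware multimodal medical image fusion: a multi-branch, multi-scale
convolutional fusion network whose training is guided by an unsupervised
per-pixel segmentation network, plus the standard suite of fusion-quality
metrics.

## Who this is for

Researchers working on pixel-level fusion of registered single-channel
medical image pairs — e.g. CT (dense structure: skull, calcifications) with
MRI (soft-tissue texture, lesions) — who want a fully inspectable, CPU-only
reference implementation of a semantic-aware fusion pipeline: feature
extraction, attention-based fusion, the joint loss, the alternating training
protocol, and the evaluation metrics, all exercisable end-to-end on seeded
synthetic phantoms without any external dataset.

## The method

**Fusion network.** Each modality is processed by three identical feature
extraction branches. A branch emits features at five scales: two stride-1
convolutions produce the full-resolution scale, then four block pairs
(a stride-2 downsampling block followed by a stride-1 block) halve the
spatial size once per scale. Every block combines a plain convolution path
with two Sobel-gradient paths using the fixed stencils Δx, Δy and the
gradient magnitude |Δx∗f| + |Δy∗f|; the second gradient stage carries a skip
connection.

Fusion runs coarse-to-fine through five fusion blocks. In each block,
sigmoid-valued attention masks modulate the features as F · (1 + M₁ + M₂),
so each multiplier lies strictly in (1, 3):

- *cross-modal attention* — each modality is weighted by its own mask and
  the other modality's mask, M = σ(Conv(ReLU(Conv(·))));
- *cross-branch attention* — channel attention from global max- and
  average-pooled descriptors through a shared bottleneck;
- *cross-scale attention* — coordinate attention (row/column average
  pooling, shared Conv–BN–hswish bottleneck) fusing the upsampled output of
  the previous (coarser) block with the current scale.

A three-layer convolutional head with a terminal sigmoid reconstructs the
fused image I_f ∈ [0,1]^{H×W}.

**Loss.** L = L_content + L_similarity + L_semantic, with

- L_content = L_int + α·L_texture, α = 5, where
  L_int = mean |I_f − max(I_ct, I_mri)| and
  L_texture = mean | |∇I_f| − max(|∇I_ct|, |∇I_mri|) | (Sobel magnitudes);
- L_similarity = 1 − [SSIM(I_f, I_ct) + SSIM(I_f, I_mri)]/2, Gaussian-
  windowed SSIM (11×11, σ = 1.5, L = 1);
- L_semantic: two photometrically jittered views of each fused image (one
  also flipped and inverse-aligned) are encoded into unit per-pixel feature
  vectors; k-means pseudo-labels per view define a soft-assignment
  cosine-distance loss within each view and across views
  (L_semantic = L_within + L_cross), enforcing photometric invariance and
  geometric equivariance of the implied segmentation.

**Training.** The fusion and segmentation networks are trained alternately —
within any epoch only one network's parameters change. The default schedule
is five cycles of (20 fusion epochs, 10 segmentation epochs), Adam, fully
seeded. The segmentation network trains from random initialization on
L_semantic alone.

**Metrics.** PSNR, average gradient (AG), spatial frequency (SF),
pixel-domain VIF, Xydeas–Petrović Qabf, Petrović artifact measure Nabf,
SSIM and 5-level MS-SSIM, each validated in the test suite against scalar
loop-based reference implementations.

Because no public dataset ships with the package, a seeded phantom generator
produces registered pairs with the complementarity structure of CT/MRI brain
slices (bright skull ring and small foci in modality A; correlated interior
texture and larger bright masses in modality B) together with ground-truth
region maps.

## Worked example

```python
import numpy as np
from semfuse import PhantomSpec, generate_pair, total_fusion_loss, evaluate_all

pair = generate_pair(PhantomSpec(height=64, width=64, seed=0))
fused = np.maximum(pair.image_a, pair.image_b)   # naive max-fusion baseline
total, parts = total_fusion_loss(fused, pair.image_a, pair.image_b)
print(f"L_total      = {float(total.data):.4f}")
print(f"L_intensity  = {parts.intensity:.4f}")
print(f"L_texture    = {parts.texture:.4f}")
print(f"L_similarity = {parts.similarity:.4f}")

report = evaluate_all(fused, pair.image_a, pair.image_b)
print(f"Qabf = {report.qabf:.4f}   SSIM = {report.ssim:.4f}   "
      f"SF = {report.sf:.4f}   Nabf = {report.nabf:.4f}")
```

prints

```
L_total      = 0.9544
L_intensity  = 0.0000
L_texture    = 0.0926
L_similarity = 0.4914
Qabf = 0.7658   SSIM = 0.5086   SF = 0.2289   Nabf = 0.0079
```

The elementwise-maximum baseline drives the intensity loss to zero by
construction; the texture and similarity terms quantify what it still misses
(gradient agreement with the stronger source, structural similarity to both
sources), and the metric row summarizes edge-information transfer (Qabf),
structural fidelity (SSIM), image sharpness (SF) and fusion artifacts (Nabf).

The CLI wraps the same library:

```bash
semfuse generate-phantoms --n 8 --size 64 --seed 0 --out data/
semfuse train --config cfg.yaml --data data/ --out run/
semfuse fuse --checkpoint run/checkpoint_final.npz \
             --input-a data/phantom_0000_A.png \
             --input-b data/phantom_0000_B.png --out fused.png
semfuse evaluate --fused run/fused --src-a data/ --src-b data/ --out report.csv
semfuse ablate --variant no-semantic --data data/ --out run_ablation/
```

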