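"""Attention-based feature fusion and reconstruction.

Five fusion blocks run coarse-to-fine, one per pyramid scale. Inside a block,
per-branch cross-modal attention merges the two modalities, cross-branch
(channel) attention merges the three branches, and — except at the coarsest
scale, which has no predecessor — cross-scale (coordinate) attention merges
the upsampled output of the previous block with the current scale. Every
attention mask is sigmoid-valued, so each multiplicative modulation
1 + M1 + M2 lies strictly inside (1, 3). A three-layer convolutional head
with a terminal sigmoid maps the finest fused features back to a [0,1] image.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .extraction import ModalityExtractor, extract_all, _as_batch
from .nn import BatchNorm2d, Conv2d, ConvBNAct, Module

__all__ = ["CrossModalAttention", "CrossBranchAttention", "CrossScaleAttention",
           "FusionBlock", "ReconstructionHead", "FusionModel", "fuse_images"]


class CrossModalAttention(Module):
    """Fuse same-branch features of the two modalities (per-scale).

    Each modality's (batch-normalized) features are modulated by its own mask
    and the other modality's mask, M = Sigmoid(Conv(ReLU(Conv(.)))); the two
    attended maps are concatenated and reduced back to `channels` by a
    pointwise convolution.
    """

    def __init__(self, channels: int, reduction_kernel: int = 1,
                 use_masks: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        self.use_masks = use_masks
        self.bn_a = BatchNorm2d(channels)
        self.bn_b = BatchNorm2d(channels)
        if use_masks:
            self.a_conv1 = Conv2d(channels, channels, 3, rng=rng)
            self.a_conv2 = Conv2d(channels, channels, 3, rng=rng)
            self.b_conv1 = Conv2d(channels, channels, 3, rng=rng)
            self.b_conv2 = Conv2d(channels, channels, 3, rng=rng)
        self.reduce = Conv2d(2 * channels, channels, reduction_kernel, rng=rng)

    def masks(self, fa_n: Tensor, fb_n: Tensor) -> tuple[Tensor, Tensor]:
        m_a = self.a_conv2(self.a_conv1(fa_n).relu()).sigmoid()
        m_b = self.b_conv2(self.b_conv1(fb_n).relu()).sigmoid()
        return m_a, m_b

    def forward(self, f_a: Tensor, f_b: Tensor) -> Tensor:
        if f_a.shape != f_b.shape:
            raise ValueError("cross-modal attention requires equal shapes")
        fa_n = self.bn_a(f_a)
        fb_n = self.bn_b(f_b)
        if self.use_masks:
            m_a, m_b = self.masks(fa_n, fb_n)
            att_a = fa_n * (1.0 + m_a + m_b)
            att_b = fb_n * (1.0 + m_b + m_a)
        else:
            att_a, att_b = fa_n, fb_n
        return self.reduce(ag.concat([att_a, att_b], axis=1))


class CrossBranchAttention(Module):
    """Fuse the three branch outputs with shared channel attention.

    Global max- and average-pooled channel descriptors pass through one shared
    two-conv bottleneck; F_bc = BN(Conv(F_b * (1 + M_max + M_avg))).
    """

    def __init__(self, channels: int, n_branches: int = 3, reduction: int = 4,
                 use_masks: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        self.use_masks = use_masks
        cat = channels * n_branches
        mid = max(cat // reduction, 1)
        if use_masks:
            self.squeeze = Conv2d(cat, mid, 1, rng=rng)
            self.excite = Conv2d(mid, cat, 1, rng=rng)
        self.reduce = Conv2d(cat, channels, 1, rng=rng)
        self.bn = BatchNorm2d(channels)

    def masks(self, f: Tensor) -> tuple[Tensor, Tensor]:
        pooled_max = f.max(axis=(2, 3), keepdims=True)
        pooled_avg = f.mean(axis=(2, 3), keepdims=True)
        m_max = self.excite(self.squeeze(pooled_max).relu()).sigmoid()
        m_avg = self.excite(self.squeeze(pooled_avg).relu()).sigmoid()
        return m_max, m_avg

    def forward(self, branch_features: list[Tensor]) -> Tensor:
        f = ag.concat(branch_features, axis=1)
        if self.use_masks:
            m_max, m_avg = self.masks(f)
            f = f * (1.0 + m_max + m_avg)
        return self.bn(self.reduce(f))


class CrossScaleAttention(Module):
    """Fuse current-scale features with processed previous-scale features.

    Coordinate attention: row descriptors (average over width) and column
    descriptors (average over height) pass through a shared Conv-BN-hswish
    bottleneck and per-direction convolutions/sigmoids, giving masks M_x and
    M_y broadcast over the missing direction;
    F_sc = BN(Conv(F_s * (1 + M_x + M_y))).
    """

    def __init__(self, channels: int, reduction: int = 4,
                 use_masks: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        self.use_masks = use_masks
        cat = 2 * channels
        mid = max(cat // reduction, 1)
        if use_masks:
            self.shared = Conv2d(cat, mid, 1, rng=rng)
            self.shared_bn = BatchNorm2d(mid)
            self.conv_x = Conv2d(mid, cat, 1, rng=rng)
            self.conv_y = Conv2d(mid, cat, 1, rng=rng)
        self.reduce = Conv2d(cat, channels, 1, rng=rng)
        self.bn = BatchNorm2d(channels)

    def masks(self, f: Tensor) -> tuple[Tensor, Tensor]:
        row_desc = f.mean(axis=3, keepdims=True)   # pool along x -> (N,C,H,1)
        col_desc = f.mean(axis=2, keepdims=True)   # pool along y -> (N,C,1,W)
        m_x = self.conv_x(self.shared_bn(self.shared(row_desc)).hswish()).sigmoid()
        m_y = self.conv_y(self.shared_bn(self.shared(col_desc)).hswish()).sigmoid()
        return m_x, m_y

    def forward(self, current: Tensor, previous: Tensor) -> Tensor:
        if current.shape[-2] < 2 or current.shape[-1] < 2:
            raise ValueError("cross-scale attention needs spatial size >= 2")
        f = ag.concat([current, previous], axis=1)
        if self.use_masks:
            m_x, m_y = self.masks(f)
            f = f * (1.0 + m_x + m_y)
        return self.bn(self.reduce(f))


class FusionBlock(Module):
    """One per-scale fusion/reconstruction block.

    Pipeline: per-branch cross-modal attention -> per-branch conv-BN-act ->
    cross-branch attention -> conv-BN-act -> (if a coarser block output
    exists) bilinear x2 upsampling, three conv-BN-act reducing the previous
    block's channels to this scale's, cross-scale attention, final
    conv-BN-act. The coarsest block has no predecessor and skips all
    cross-scale processing.
    """

    def __init__(self, channels: int, prev_channels: int | None,
                 n_branches: int = 3, slope: float = 0.01,
                 reduction_kernel: int = 1, use_attention: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.n_branches = n_branches
        self.prev_channels = prev_channels
        for b in range(n_branches):
            setattr(self, f"cmam{b}",
                    CrossModalAttention(channels, reduction_kernel,
                                        use_masks=use_attention, rng=rng))
            setattr(self, f"branch_conv{b}",
                    ConvBNAct(channels, channels, 3, slope=slope, rng=rng))
        self.cbam = CrossBranchAttention(channels, n_branches,
                                         use_masks=use_attention, rng=rng)
        self.post_branch = ConvBNAct(channels, channels, 3, slope=slope, rng=rng)
        if prev_channels is not None:
            steps = np.linspace(prev_channels, channels, 4).round().astype(int)
            self.prev_conv0 = ConvBNAct(int(steps[0]), int(steps[1]), 3,
                                        slope=slope, rng=rng)
            self.prev_conv1 = ConvBNAct(int(steps[1]), int(steps[2]), 3,
                                        slope=slope, rng=rng)
            self.prev_conv2 = ConvBNAct(int(steps[2]), int(steps[3]), 3,
                                        slope=slope, rng=rng)
            self.csam = CrossScaleAttention(channels, use_masks=use_attention,
                                            rng=rng)
            self.post_scale = ConvBNAct(channels, channels, 3, slope=slope,
                                        rng=rng)

    def forward(self, feats_a: list[Tensor], feats_b: list[Tensor],
                previous: Tensor | None = None) -> Tensor:
        if len(feats_a) != self.n_branches or len(feats_b) != self.n_branches:
            raise ValueError(
                f"fusion block expects {self.n_branches} branch features")
        fused_branches = []
        for b in range(self.n_branches):
            fused = getattr(self, f"cmam{b}")(feats_a[b], feats_b[b])
            fused_branches.append(getattr(self, f"branch_conv{b}")(fused))
        x = self.post_branch(self.cbam(fused_branches))
        if self.prev_channels is None:
            return x
        if previous is None:
            raise ValueError("block with a coarser predecessor needs its output")
        prev = ag.upsample_bilinear(previous, 2)
        prev = self.prev_conv2(self.prev_conv1(self.prev_conv0(prev)))
        return self.post_scale(self.csam(x, prev))


class ReconstructionHead(Module):
    """Three 3x3 convolutions mapping fused features to a [0,1] image."""

    def __init__(self, channels: int, slope: float = 0.01,
                 rng: np.random.Generator | None = None):
        super().__init__()
        mid1 = max(channels // 2, 4)
        mid2 = max(channels // 4, 4)
        self.conv1 = ConvBNAct(channels, mid1, 3, slope=slope, rng=rng)
        self.conv2 = ConvBNAct(mid1, mid2, 3, slope=slope, rng=rng)
        self.conv3 = Conv2d(mid2, 1, 3, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.conv3(self.conv2(self.conv1(x))).sigmoid()


class FusionModel(Module):
    """End-to-end fusion network: extractors, fusion blocks, reconstruction."""

    def __init__(self, channels: tuple[int, ...] = (16, 32, 64, 128, 256),
                 n_branches: int = 3, n_scales: int = 5, slope: float = 0.01,
                 reduction_kernel: int = 1, use_attention: bool = True,
                 share_extractors: bool = False, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.n_scales = n_scales
        self.n_branches = n_branches
        self.channels = tuple(channels[:n_scales])
        self.share_extractors = share_extractors
        self.extractor_a = ModalityExtractor(channels, slope, n_branches,
                                             n_scales, rng=rng)
        if share_extractors:
            self.extractor_b = self.extractor_a
        else:
            self.extractor_b = ModalityExtractor(channels, slope, n_branches,
                                                 n_scales, rng=rng)
        for i in range(n_scales):
            prev = self.channels[i + 1] if i + 1 < n_scales else None
            setattr(self, f"block{i}",
                    FusionBlock(self.channels[i], prev, n_branches, slope,
                                reduction_kernel, use_attention, rng=rng))
        self.head = ReconstructionHead(self.channels[0], slope, rng=rng)

    @property
    def fusion_blocks(self) -> list[FusionBlock]:
        return [getattr(self, f"block{i}") for i in range(self.n_scales)]

    def forward(self, image_a: Tensor | np.ndarray,
                image_b: Tensor | np.ndarray) -> Tensor:
        feats_a, feats_b = extract_all(image_a, image_b,
                                       self.extractor_a, self.extractor_b)
        previous: Tensor | None = None
        for i in reversed(range(self.n_scales)):   # coarse to fine
            block = getattr(self, f"block{i}")
            a_i = [feats_a[b][i] for b in range(self.n_branches)]
            b_i = [feats_b[b][i] for b in range(self.n_branches)]
            previous = block(a_i, b_i, previous)
        return self.head(previous)

    def fuse(self, image_a: np.ndarray, image_b: np.ndarray) -> np.ndarray:
        """Forward pass in eval mode on numpy images; returns a 2-D image."""
        was_training = self.training
        self.eval()
        with ag.no_grad():
            fused = self.forward(_as_batch(image_a), _as_batch(image_b))
        if was_training:
            self.train()
        out = fused.numpy()
        return out[0, 0] if np.ndim(image_a) == 2 else out[:, 0]


def fuse_images(image_a: np.ndarray, image_b: np.ndarray,
                model: FusionModel) -> np.ndarray:
    """Fuse one registered pair with a trained (or initialized) model."""
    if image_a.shape != image_b.shape:
        raise ValueError("images must be registered to equal sizes")
    return model.fuse(image_a, image_b)
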