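"""Multi-branch, multi-scale feature extraction with Sobel-gradient blocks.

Each modality is processed by three identical (but independently initialized)
branches. A branch applies two stride-1 convolutions to produce the
full-resolution scale-0 features, then four (downsampling block, plain block)
pairs, each pair halving the spatial size exactly once, yielding a five-level
feature pyramid. Every feature-extraction block combines a standard
convolution path with two Sobel-gradient paths: the gradient magnitude
|Δx∗f| + |Δy∗f| is computed depthwise with the fixed Sobel stencils and
passed through a learned convolution, the second gradient stage carrying a
skip connection to keep gradients well-behaved.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .nn import Conv2d, Module

__all__ = ["SOBEL_KX", "SOBEL_KY", "sobel_gradient", "FeatureExtractBlock",
           "ExtractionBranch", "ModalityExtractor", "extract_all"]

# Horizontal / vertical Sobel stencils (rows and columns sum to zero).
SOBEL_KX = np.array([[-1.0, 0.0, 1.0],
                     [-2.0, 0.0, 2.0],
                     [-1.0, 0.0, 1.0]])
SOBEL_KY = SOBEL_KX.T.copy()

_SOBEL_WEIGHT = Tensor(np.stack([SOBEL_KX, SOBEL_KY])[:, None, :, :])


def sobel_gradient(x: Tensor | np.ndarray) -> Tensor:
    """Depthwise Sobel gradient magnitude |Δx∗f| + |Δy∗f|.

    Accepts (H,W), (C,H,W) or (N,C,H,W); reflective border padding; output
    has the input's shape and is non-negative everywhere.
    """
    t = ag.as_tensor(x)
    shape = t.shape
    if t.ndim == 2:
        t = t.reshape(1, 1, *shape)
    elif t.ndim == 3:
        t = t.reshape(1, *shape)
    elif t.ndim != 4:
        raise ValueError("sobel_gradient expects 2-D, 3-D or 4-D input")
    n, c, h, w = t.shape
    if h < 3 or w < 3:
        raise ValueError("sobel_gradient needs spatial size >= 3x3")
    flat = t.reshape(n * c, 1, h, w)
    resp = ag.conv2d(flat, _SOBEL_WEIGHT, padding=1)     # (N*C, 2, H, W)
    mag = resp.abs().sum(axis=1, keepdims=True)
    return mag.reshape(shape)


class FeatureExtractBlock(Module):
    """Plain-conv path plus two Sobel-gradient paths, summed under LeakyReLU.

    out = LeakyReLU(plain(x) + s1 + s2) with
    s1 = Conv(sobel(x)), s2 = Conv(sobel(s1)) + s1 (skip connection).
    `stride` > 1 downsamples (applied in the plain path and the first
    gradient convolution; the second stage operates at the reduced size).
    """

    def __init__(self, in_channels: int, out_channels: int, stride: int = 1,
                 slope: float = 0.01, rng: np.random.Generator | None = None):
        super().__init__()
        self.slope = slope
        self.plain = Conv2d(in_channels, out_channels, 3, stride, rng=rng)
        self.grad1 = Conv2d(in_channels, out_channels, 3, stride, rng=rng)
        self.grad2 = Conv2d(out_channels, out_channels, 3, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        p = self.plain(x)
        s1 = self.grad1(sobel_gradient(x))
        s2 = self.grad2(sobel_gradient(s1)) + s1
        return (p + s1 + s2).leaky_relu(self.slope)


class ExtractionBranch(Module):
    """One feature-extraction branch emitting a five-level pyramid."""

    def __init__(self, channels: tuple[int, ...] = (16, 32, 64, 128, 256),
                 slope: float = 0.01, n_scales: int = 5,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if len(channels) < n_scales:
            raise ValueError("need one channel width per scale")
        if any(channels[i] > channels[i + 1] for i in range(n_scales - 1)):
            raise ValueError("channel widths must be non-decreasing")
        self.n_scales = n_scales
        self.channels = tuple(channels[:n_scales])
        self.slope = slope
        self.conv0a = Conv2d(1, channels[0], 3, 1, rng=rng)
        self.conv0b = Conv2d(channels[0], channels[0], 3, 1, rng=rng)
        for i in range(1, n_scales):
            setattr(self, f"down{i}",
                    FeatureExtractBlock(channels[i - 1], channels[i],
                                        stride=2, slope=slope, rng=rng))
            setattr(self, f"block{i}",
                    FeatureExtractBlock(channels[i], channels[i],
                                        stride=1, slope=slope, rng=rng))

    def forward(self, image: Tensor) -> list[Tensor]:
        h, w = image.shape[-2], image.shape[-1]
        div = 2 ** (self.n_scales - 1)
        if h % div or w % div:
            raise ValueError(f"input size must be divisible by {div}")
        if h < 3 * div or w < 3 * div:
            # the coarsest level must stay >= 3x3 for the Sobel stencils
            raise ValueError(f"input size must be at least {3 * div} pixels")
        x = self.conv0a(image).leaky_relu(self.slope)
        x = self.conv0b(x).leaky_relu(self.slope)
        levels = [x]
        for i in range(1, self.n_scales):
            x = getattr(self, f"block{i}")(getattr(self, f"down{i}")(x))
            levels.append(x)
        return levels


class ModalityExtractor(Module):
    """Three identical branches for one modality."""

    def __init__(self, channels: tuple[int, ...] = (16, 32, 64, 128, 256),
                 slope: float = 0.01, n_branches: int = 3, n_scales: int = 5,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.n_branches = n_branches
        self.n_scales = n_scales
        self.channels = tuple(channels[:n_scales])
        for b in range(n_branches):
            setattr(self, f"branch{b}",
                    ExtractionBranch(channels, slope, n_scales, rng=rng))

    def forward(self, image: Tensor) -> list[list[Tensor]]:
        return [getattr(self, f"branch{b}")(image)
                for b in range(self.n_branches)]


def extract_all(image_a: Tensor | np.ndarray, image_b: Tensor | np.ndarray,
                extractor_a: ModalityExtractor,
                extractor_b: ModalityExtractor,
                ) -> tuple[list[list[Tensor]], list[list[Tensor]]]:
    """Run both modality extractors; returns 3 pyramids per modality."""
    a = _as_batch(image_a)
    b = _as_batch(image_b)
    if a.shape != b.shape:
        raise ValueError("registered images must have equal sizes")
    return extractor_a(a), extractor_b(b)


def _as_batch(x: Tensor | np.ndarray) -> Tensor:
    t = ag.as_tensor(x)
    if t.ndim == 2:
        t = t.reshape(1, 1, *t.shape)
    elif t.ndim == 3:
        t = t.reshape(t.shape[0], 1, t.shape[1], t.shape[2])
    return t
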