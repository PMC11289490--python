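"""Fusion losses: intensity, texture, content, SSIM similarity, and the total.

The fused image is pulled toward the elementwise maximum of the sources in
intensity and in Sobel gradient magnitude (content loss, with texture weight
alpha), toward both sources in windowed structural similarity (similarity
loss), and toward semantically consistent clusterings (semantic loss,
supplied by the segmentation module). Total = content + similarity +
semantic. All losses accept numpy arrays or autograd tensors, operate on
(H,W), (N,H,W) or (N,1,H,W) inputs, and are differentiable with respect to
the fused image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .extraction import sobel_gradient

__all__ = ["LossBreakdown", "intensity_loss", "texture_loss", "content_loss",
           "ssim", "similarity_loss", "total_fusion_loss", "gaussian_window"]

DEFAULT_ALPHA = 5.0


@dataclass
class LossBreakdown:
    """Scalar record of the total loss and its components."""

    total: float
    content: float
    intensity: float
    texture: float
    alpha: float
    similarity: float
    semantic: float
    within: float = 0.0
    cross: float = 0.0

    def as_dict(self) -> dict[str, float]:
        return {"L": self.total, "L_content": self.content,
                "L_int": self.intensity, "L_texture": self.texture,
                "alpha": self.alpha, "L_similarity": self.similarity,
                "L_semantic": self.semantic, "L_within": self.within,
                "L_cross": self.cross}


def _prep(*images) -> list[Tensor]:
    ts = [ag.as_tensor(im) for im in images]
    shapes = {t.shape for t in ts}
    if len(shapes) != 1:
        raise ValueError(f"loss inputs must share shapes, got {shapes}")
    out = []
    for t in ts:
        if t.ndim == 2:
            t = t.reshape(1, 1, *t.shape)
        elif t.ndim == 3:
            t = t.reshape(t.shape[0], 1, t.shape[1], t.shape[2])
        elif t.ndim != 4:
            raise ValueError("loss inputs must be 2-D, 3-D or 4-D")
        out.append(t)
    return out


def intensity_loss(i_f, i_ct, i_mri) -> Tensor:
    """Mean L1 distance between I_f and max(I_ct, I_mri) (per pixel)."""
    f, a, b = _prep(i_f, i_ct, i_mri)
    return (f - ag.maximum(a, b)).abs().mean()


def texture_loss(i_f, i_ct, i_mri) -> Tensor:
    """Mean L1 distance between |∇I_f| and max(|∇I_ct|, |∇I_mri|).

    ∇ is the Sobel gradient magnitude (sum of absolute directional responses),
    the same operator the extraction blocks use.
    """
    f, a, b = _prep(i_f, i_ct, i_mri)
    gf = sobel_gradient(f)
    ga = sobel_gradient(a)
    gb = sobel_gradient(b)
    return (gf - ag.maximum(ga, gb)).abs().mean()


def content_loss(i_f, i_ct, i_mri, alpha: float = DEFAULT_ALPHA) -> Tensor:
    """Intensity loss plus alpha times texture loss (alpha defaults to 5)."""
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    return intensity_loss(i_f, i_ct, i_mri) \
        + alpha * texture_loss(i_f, i_ct, i_mri)


def gaussian_window(size: int = 11, sigma: float = 1.5) -> np.ndarray:
    """Normalized 2-D Gaussian window used for SSIM statistics."""
    ax = np.arange(size) - (size - 1) / 2.0
    g = np.exp(-(ax ** 2) / (2.0 * sigma ** 2))
    w = np.outer(g, g)
    return w / w.sum()


def ssim(x, y, window_size: int = 11, sigma: float = 1.5,
         dynamic_range: float = 1.0) -> Tensor:
    """Mean structural similarity index over Gaussian-weighted windows.

    SSIM = (2 μx μy + c1)(2 σxy + c2) / ((μx² + μy² + c1)(σx² + σy² + c2))
    with c1 = (0.01 L)², c2 = (0.03 L)²; 1 for identical images; symmetric.
    The window shrinks (to the nearest odd size) when the image is smaller
    than 11 pixels along an axis.
    """
    if dynamic_range <= 0:
        raise ValueError("dynamic range L must be positive")
    xt, yt = _prep(x, y)
    h, w = xt.shape[-2], xt.shape[-1]
    win = min(window_size, h, w)
    if win % 2 == 0:
        win -= 1
    if win < 1:
        raise ValueError("image too small for SSIM window")
    kernel = Tensor(gaussian_window(win, sigma)[None, None])
    c1 = (0.01 * dynamic_range) ** 2
    c2 = (0.03 * dynamic_range) ** 2

    def filt(t: Tensor) -> Tensor:
        return ag.conv2d(t, kernel, stride=1, padding=0)

    mu_x = filt(xt)
    mu_y = filt(yt)
    mu_xx = mu_x * mu_x
    mu_yy = mu_y * mu_y
    mu_xy = mu_x * mu_y
    var_x = filt(xt * xt) - mu_xx
    var_y = filt(yt * yt) - mu_yy
    cov_xy = filt(xt * yt) - mu_xy
    num = (2.0 * mu_xy + c1) * (2.0 * cov_xy + c2)
    den = (mu_xx + mu_yy + c1) * (var_x + var_y + c2)
    return (num / den).mean()


def similarity_loss(i_f, i_ct, i_mri, dynamic_range: float = 1.0) -> Tensor:
    """1 - [SSIM(I_f, I_ct) + SSIM(I_f, I_mri)] / 2; lies in [0, 2]."""
    f, a, b = _prep(i_f, i_ct, i_mri)
    return 1.0 - (ssim(f, a, dynamic_range=dynamic_range)
                  + ssim(f, b, dynamic_range=dynamic_range)) * 0.5


def total_fusion_loss(i_f, i_ct, i_mri, semantic_value=0.0,
                      alpha: float = DEFAULT_ALPHA,
                      semantic_within: float = 0.0,
                      semantic_cross: float = 0.0,
                      ) -> tuple[Tensor, LossBreakdown]:
    """Assemble total = content + similarity + semantic.

    `semantic_value` may be a float (e.g. 0 in ablations) or a Tensor from the
    segmentation module, keeping the term differentiable.
    """
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    l_int = intensity_loss(i_f, i_ct, i_mri)
    l_tex = texture_loss(i_f, i_ct, i_mri)
    l_content = l_int + alpha * l_tex
    l_sim = similarity_loss(i_f, i_ct, i_mri)
    l_sem = ag.as_tensor(semantic_value)
    if float(l_sem.data) < 0:
        raise ValueError("semantic loss must be non-negative")
    total = l_content + l_sim + l_sem
    breakdown = LossBreakdown(
        total=float(total.data), content=float(l_content.data),
        intensity=float(l_int.data), texture=float(l_tex.data),
        alpha=alpha, similarity=float(l_sim.data),
        semantic=float(l_sem.data), within=semantic_within,
        cross=semantic_cross)
    return total, breakdown
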