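"""Fusion-quality metrics: PSNR, AG, SF, VIF, Qabf, Nabf, SSIM, MS-SSIM.

The gradient-based fusion measures follow the canonical published
formulations: the Xydeas-Petrović edge-preservation metric for Qabf
(Sobel strength and orientation, sigmoid-mapped preservation, gradient-
strength weighting) and the Petrović fusion-artifact measure for Nabf
(preservation deficit over locations whose fused gradient exceeds both
source gradients). VIF is the pixel-domain (multi-scale GSM) variant.
Two-reference metrics are aggregated over the two sources by arithmetic
mean by default ('mean' mode; 'max' is also available).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .autograd import Tensor
from .losses import gaussian_window, ssim as _ssim_tensor

__all__ = ["MetricReport", "psnr", "average_gradient", "spatial_frequency",
           "ssim_index", "msssim", "vif", "qabf", "nabf", "evaluate_all",
           "report_to_csv", "MSSSIM_WEIGHTS"]

MSSSIM_WEIGHTS = (0.0448, 0.2856, 0.3001, 0.2363, 0.1333)

REPORT_COLUMNS = ["id", "psnr", "vif", "ag", "qabf", "sf", "nabf",
                  "ssim", "msssim"]


@dataclass
class MetricReport:
    """One scalar per metric for a (fused, source A, source B) triple."""

    psnr: float
    vif: float
    ag: float
    qabf: float
    sf: float
    nabf: float
    ssim: float
    msssim: float

    def as_row(self, image_id: str = "") -> dict:
        row = {"id": image_id}
        row.update({k: getattr(self, k) for k in REPORT_COLUMNS[1:]})
        return row


def _check_pair(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    return x, y


def psnr(fused: np.ndarray, reference: np.ndarray,
         dynamic_range: float = 1.0) -> float:
    """10 log10(L^2 / MSE), +inf when the images are identical."""
    fused, reference = _check_pair(fused, reference)
    mse = float(np.mean((fused - reference) ** 2))
    if mse == 0.0:
        return float("inf")
    return float(10.0 * np.log10(dynamic_range ** 2 / mse))


def average_gradient(image: np.ndarray) -> float:
    """Mean of sqrt((Δh² + Δv²)/2) over forward-difference pixels."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or min(image.shape) < 2:
        raise ValueError("average gradient needs a 2-D image of size >= 2x2")
    dh = image[:, 1:] - image[:, :-1]
    dv = image[1:, :] - image[:-1, :]
    dh = dh[:-1, :]
    dv = dv[:, :-1]
    return float(np.mean(np.sqrt((dh ** 2 + dv ** 2) / 2.0)))


def spatial_frequency(image: np.ndarray) -> float:
    """sqrt(RF² + CF²) from RMS row and column first differences."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or min(image.shape) < 2:
        raise ValueError("spatial frequency needs a 2-D image of size >= 2x2")
    rf2 = np.mean((image[:, 1:] - image[:, :-1]) ** 2)
    cf2 = np.mean((image[1:, :] - image[:-1, :]) ** 2)
    return float(np.sqrt(rf2 + cf2))


def ssim_index(x: np.ndarray, y: np.ndarray, dynamic_range: float = 1.0,
               window_size: int = 11, sigma: float = 1.5) -> float:
    """Gaussian-windowed mean SSIM (shared implementation with the loss)."""
    x, y = _check_pair(x, y)
    return float(_ssim_tensor(Tensor(x), Tensor(y), window_size=window_size,
                              sigma=sigma, dynamic_range=dynamic_range).data)


def _downsample2(x: np.ndarray) -> np.ndarray:
    h, w = x.shape
    x = x[: h - h % 2, : w - w % 2]
    return 0.25 * (x[0::2, 0::2] + x[1::2, 0::2] + x[0::2, 1::2]
                   + x[1::2, 1::2])


def msssim(x: np.ndarray, y: np.ndarray, dynamic_range: float = 1.0,
           levels: int = 5, weights: tuple[float, ...] = MSSSIM_WEIGHTS,
           window_size: int = 11, sigma: float = 1.5) -> float:
    """Multi-scale SSIM: product of contrast-structure terms over dyadic
    scales, with the full SSIM at the coarsest scale, standard exponents
    (0.0448, 0.2856, 0.3001, 0.2363, 0.1333). levels=1 reduces to SSIM.

    The window shrinks at coarse levels so small images support 5 levels.
    """
    x, y = _check_pair(x, y)
    if levels < 1 or (levels != 1 and levels > len(weights)):
        raise ValueError("unsupported number of levels")
    w = (1.0,) if levels == 1 else weights[:levels]
    if min(x.shape) < 2 ** (levels - 1) * 2:
        raise ValueError("image too small for the requested level count")
    value = 1.0
    for lev in range(levels):
        h, wd = x.shape
        win = min(window_size, h, wd)
        if win % 2 == 0:
            win -= 1
        kernel = gaussian_window(win, sigma)
        c1 = (0.01 * dynamic_range) ** 2
        c2 = (0.03 * dynamic_range) ** 2

        def filt(t):
            return fftconvolve(t, kernel, mode="valid")

        mu_x, mu_y = filt(x), filt(y)
        var_x = filt(x * x) - mu_x ** 2
        var_y = filt(y * y) - mu_y ** 2
        cov = filt(x * y) - mu_x * mu_y
        cs = (2 * cov + c2) / (var_x + var_y + c2)
        if lev == levels - 1:
            lum = (2 * mu_x * mu_y + c1) / (mu_x ** 2 + mu_y ** 2 + c1)
            value *= float(np.mean(lum * cs)) ** w[lev] if np.mean(lum * cs) > 0 \
                else 0.0
        else:
            mcs = float(np.mean(cs))
            if mcs <= 0:
                return 0.0
            value *= mcs ** w[lev]
            x, y = _downsample2(x), _downsample2(y)
    return float(value)


def vif(fused: np.ndarray, reference: np.ndarray,
        sigma_nsq: float = 2.0) -> float:
    """Pixel-domain visual information fidelity (four dyadic scales).

    Ratio of the visual information the test image preserves about the
    reference to the reference's own information content under a Gaussian
    scale mixture model; equals 1 when fused == reference. Scales whose
    subband is smaller than its window are dropped; images must support at
    least the finest scale.
    """
    ref, dist = _check_pair(reference, fused)
    if min(ref.shape) < 17:
        raise ValueError("image too small for the VIF pyramid")
    num = 0.0
    den = 0.0
    for scale in range(1, 5):
        n = 2 ** (4 - scale + 1) + 1
        kernel = gaussian_window(n, n / 5.0)
        if scale > 1:
            ref = fftconvolve(ref, kernel, mode="valid")[::2, ::2]
            dist = fftconvolve(dist, kernel, mode="valid")[::2, ::2]
        if min(ref.shape) < n:
            break
        mu1 = fftconvolve(ref, kernel, mode="valid")
        mu2 = fftconvolve(dist, kernel, mode="valid")
        sigma1_sq = fftconvolve(ref * ref, kernel, mode="valid") - mu1 ** 2
        sigma2_sq = fftconvolve(dist * dist, kernel, mode="valid") - mu2 ** 2
        sigma12 = fftconvolve(ref * dist, kernel, mode="valid") - mu1 * mu2
        sigma1_sq = np.maximum(sigma1_sq, 0.0)
        sigma2_sq = np.maximum(sigma2_sq, 0.0)

        g = sigma12 / (sigma1_sq + 1e-10)
        sv_sq = sigma2_sq - g * sigma12
        g[sigma1_sq < 1e-10] = 0.0
        sv_sq[sigma1_sq < 1e-10] = sigma2_sq[sigma1_sq < 1e-10]
        sigma1_sq[sigma1_sq < 1e-10] = 0.0
        g[g < 0] = 0.0
        sv_sq[sv_sq <= 1e-10] = 1e-10

        num += float(np.sum(np.log10(1.0 + g ** 2 * sigma1_sq
                                     / (sv_sq + sigma_nsq))))
        den += float(np.sum(np.log10(1.0 + sigma1_sq / sigma_nsq)))
    if den == 0.0:
        return 1.0 if num == 0.0 else 0.0
    return float(num / den)


# ------------------------------------------------------- gradient measures
_SOBEL_GX = np.array([[-1.0, 0.0, 1.0], [-2.0, 0.0, 2.0], [-1.0, 0.0, 1.0]])
_SOBEL_GY = _SOBEL_GX.T

# Xydeas-Petrović sigmoid constants (strength / orientation)
_QABF_GAMMA_G, _QABF_KG, _QABF_DG = 0.9994, -15.0, 0.5
_QABF_GAMMA_A, _QABF_KA, _QABF_DA = 0.9879, -22.0, 0.8


def _sobel_same(img: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # direct (non-FFT) correlation so constant images give exactly zero
    pad = np.pad(img, 1, mode="reflect")
    win = np.lib.stride_tricks.sliding_window_view(pad, (3, 3))
    gx = np.einsum("ijkl,kl->ij", win, _SOBEL_GX)
    gy = np.einsum("ijkl,kl->ij", win, _SOBEL_GY)
    return gx, gy


def _edge_strength_angle(img: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    gx, gy = _sobel_same(img)
    g = np.sqrt(gx ** 2 + gy ** 2)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        alpha = np.where(gx == 0, np.sign(gy) * np.pi / 2.0,
                         np.arctan(np.where(gx == 0, 1.0, gy / gx)))
    return g, alpha


def _preservation(g_src, a_src, g_f, a_f):
    """Sigmoid-mapped strength and orientation preservation Q^{sF}."""
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(g_src > g_f,
                         np.where(g_src == 0, 0.0, g_f / g_src),
                         np.where(g_f == 0, 0.0, g_src / g_f))
    ratio = np.where((g_src == 0) & (g_f == 0), 0.0, ratio)
    ratio = np.where(g_src == g_f, np.where(g_src == 0, 0.0, 1.0), ratio)
    qg = _QABF_GAMMA_G / (1.0 + np.exp(_QABF_KG * (ratio - _QABF_DG)))
    aaf = 1.0 - np.abs(a_src - a_f) / (np.pi / 2.0)
    qa = _QABF_GAMMA_A / (1.0 + np.exp(_QABF_KA * (aaf - _QABF_DA)))
    return qg * qa


def qabf(fused: np.ndarray, a: np.ndarray, b: np.ndarray,
         weight_exponent: float = 1.0) -> float:
    """Xydeas-Petrović gradient-preservation measure Q^{AB/F} in [0,1].

    Flat inputs (zero gradient energy everywhere) give 0 by convention.
    """
    fused, a = _check_pair(fused, a)
    fused, b = _check_pair(fused, b)
    g_f, a_f = _edge_strength_angle(fused)
    g_a, a_a = _edge_strength_angle(a)
    g_b, a_b = _edge_strength_angle(b)
    q_af = _preservation(g_a, a_a, g_f, a_f)
    q_bf = _preservation(g_b, a_b, g_f, a_f)
    w_a = g_a ** weight_exponent
    w_b = g_b ** weight_exponent
    den = float(np.sum(w_a + w_b))
    if den == 0.0:
        return 0.0
    return float(np.sum(q_af * w_a + q_bf * w_b) / den)


def nabf(fused: np.ndarray, a: np.ndarray, b: np.ndarray,
         weight_exponent: float = 1.0) -> float:
    """Petrović fusion-artifact measure: preservation deficit over locations
    whose fused gradient exceeds both source gradients; 0 for perfect
    self-fusion, larger when the fused image contains edge energy absent
    from both sources. Flat inputs give 0 by convention.
    """
    fused, a = _check_pair(fused, a)
    fused, b = _check_pair(fused, b)
    g_f, a_f = _edge_strength_angle(fused)
    g_a, a_a = _edge_strength_angle(a)
    g_b, a_b = _edge_strength_angle(b)
    q_af = _preservation(g_a, a_a, g_f, a_f)
    q_bf = _preservation(g_b, a_b, g_f, a_f)
    am = (g_f > g_a) & (g_f > g_b)
    w_a = g_a ** weight_exponent
    w_b = g_b ** weight_exponent
    den = float(np.sum(w_a + w_b))
    if den == 0.0:
        return float(np.mean(am.astype(float))) if am.any() else 0.0
    return float(np.sum(am * ((1.0 - q_af) * w_a + (1.0 - q_bf) * w_b)) / den)


def evaluate_all(fused: np.ndarray, a: np.ndarray, b: np.ndarray,
                 mode: str = "mean") -> MetricReport:
    """All eight metrics for one triple.

    Two-reference metrics (psnr, ssim, msssim, vif) are aggregated over the
    sources with `mode` ('mean' or 'max'); ag and sf are computed on the
    fused image alone; qabf and nabf use the full triple.
    """
    if mode not in ("mean", "max"):
        raise ValueError("mode must be 'mean' or 'max'")
    agg = np.mean if mode == "mean" else np.max

    def both(fn):
        return float(agg([fn(fused, a), fn(fused, b)]))

    return MetricReport(
        psnr=both(psnr),
        vif=both(vif),
        ag=average_gradient(fused),
        qabf=qabf(fused, a, b),
        sf=spatial_frequency(fused),
        nabf=nabf(fused, a, b),
        ssim=both(ssim_index),
        msssim=both(msssim),
    )


def report_to_csv(reports: dict[str, MetricReport], path: str | Path) -> Path:
    """Write per-image metric rows (Table-style column order) to CSV."""
    rows = [rep.as_row(image_id) for image_id, rep in reports.items()]
    pd.DataFrame(rows, columns=REPORT_COLUMNS).to_csv(path, index=False)
    return Path(path)
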