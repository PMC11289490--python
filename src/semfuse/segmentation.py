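"""Unsupervised per-pixel segmentation supplying the semantic loss.

A lightweight convolutional encoder-decoder maps an image to a unit-norm
feature vector per pixel. Two photometrically jittered views of each fused
image (one additionally geometrically transformed and inverse-aligned) are
encoded, the pooled per-pixel features of each view are clustered
independently with k-means, and the cluster assignments act as pseudo-labels:
the within-view loss pulls each feature toward its own view's center, the
cross-view loss toward the other view's center, enforcing photometric
invariance and geometric equivariance of the labeling. Pseudo-labels and
centers are constants within a step (stop-gradient); gradients reach the
network weights only through the features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .nn import Conv2d, Module

__all__ = ["PhotometricJitter", "photometric_transform", "geometric_transform",
           "inverse_geometric", "SegmentationNet", "seg_forward", "kmeans",
           "ClusterState", "cluster_views", "clust_loss", "semantic_loss"]


@dataclass(frozen=True)
class PhotometricJitter:
    """Bounds of the random brightness/contrast/gamma jitter.

    brightness: additive offset drawn from [-b, b];
    contrast: multiplicative factor from [1-c, 1+c];
    gamma: exponent from [1-g, 1+g]. Zero bounds give the identity.
    """

    brightness: float = 0.1
    contrast: float = 0.1
    gamma: float = 0.2

    def __post_init__(self):
        if not (0 <= self.brightness <= 1 and 0 <= self.contrast < 1
                and 0 <= self.gamma < 1):
            raise ValueError("jitter bounds must lie in [0,1)")

    def draw(self, rng: np.random.Generator) -> tuple[float, float, float]:
        return (float(rng.uniform(-self.brightness, self.brightness)),
                float(rng.uniform(1 - self.contrast, 1 + self.contrast)),
                float(rng.uniform(1 - self.gamma, 1 + self.gamma)))


_GAMMA_EPS = 1e-6


def _apply_photometric(x: Tensor, brightness: float, contrast: float,
                       gamma: float) -> Tensor:
    """Differentiable jitter: clip(contrast * (x+eps)^gamma + brightness).

    The epsilon keeps the gamma curve differentiable at zero; it is skipped
    when gamma is exactly 1 so the degenerate transform is the identity.
    """
    if gamma != 1.0:
        x = (x + _GAMMA_EPS) ** gamma
    return (x * contrast + brightness).clip(0.0, 1.0)


def photometric_transform(image: np.ndarray, seed: int,
                          jitter: PhotometricJitter = PhotometricJitter(),
                          ) -> np.ndarray:
    """Seeded random brightness/contrast/gamma jitter of a [0,1] image."""
    image = np.asarray(image, dtype=np.float64)
    if image.min() < 0 or image.max() > 1:
        raise ValueError("photometric transform expects intensities in [0,1]")
    b, c, g = jitter.draw(np.random.default_rng(seed))
    return _apply_photometric(Tensor(image), b, c, g).numpy()


def geometric_transform(field: np.ndarray, params: dict) -> np.ndarray:
    """Apply {'hflip': bool, 'scale': int>=1} to an (..., H, W) field.

    Rescaling is nearest-neighbour (exactly invertible on the grid); label
    fields keep their dtype.
    """
    scale = int(params.get("scale", 1))
    if scale < 1:
        raise ValueError("scale factor must be a positive integer")
    out = np.asarray(field)
    if params.get("hflip", False):
        out = np.flip(out, axis=-1)
    if scale > 1:
        out = np.repeat(np.repeat(out, scale, axis=-2), scale, axis=-1)
    return out.copy()


def inverse_geometric(field: np.ndarray, params: dict) -> np.ndarray:
    """Inverse of geometric_transform on the pixel grid."""
    scale = int(params.get("scale", 1))
    if scale < 1:
        raise ValueError("scale factor must be a positive integer")
    out = np.asarray(field)
    if scale > 1:
        out = out[..., ::scale, ::scale]
    if params.get("hflip", False):
        out = np.flip(out, axis=-1)
    return out.copy()


def _geometric_tensor(x: Tensor, params: dict) -> Tensor:
    if params.get("hflip", False):
        x = x.flip(-1)
    scale = int(params.get("scale", 1))
    if scale > 1:
        x = x.repeat(scale, axis=-2).repeat(scale, axis=-1)
    return x


def _inverse_geometric_tensor(x: Tensor, params: dict) -> Tensor:
    scale = int(params.get("scale", 1))
    if scale > 1:
        x = x[..., ::scale, ::scale]
    if params.get("hflip", False):
        x = x.flip(-1)
    return x


class SegmentationNet(Module):
    """Small conv encoder (two stride-2 stages) with bilinear decoding.

    Emits a D-dimensional L2-normalized feature vector per pixel. Input
    spatial size must be divisible by 4.
    """

    def __init__(self, feature_dim: int = 32, hidden: int = 16, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.feature_dim = feature_dim
        self.enc1 = Conv2d(1, hidden, 3, 1, rng=rng)
        self.enc2 = Conv2d(hidden, 2 * hidden, 3, 2, rng=rng)
        self.enc3 = Conv2d(2 * hidden, 2 * hidden, 3, 2, rng=rng)
        self.enc4 = Conv2d(2 * hidden, 2 * hidden, 3, 1, rng=rng)
        self.head = Conv2d(2 * hidden, feature_dim, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        h, w = x.shape[-2], x.shape[-1]
        if h % 4 or w % 4:
            raise ValueError("segmentation input size must be divisible by 4")
        z = self.enc1(x).relu()
        z = self.enc2(z).relu()
        z = self.enc3(z).relu()
        z = self.enc4(z).relu()
        z = ag.upsample_bilinear(z, 4)
        z = self.head(z)
        norm = ((z * z).sum(axis=1, keepdims=True) + 1e-12) ** 0.5
        return z / norm


def seg_forward(image: Tensor | np.ndarray, net: SegmentationNet) -> Tensor:
    """Per-pixel unit feature field (N, D, H, W) for an image batch."""
    t = ag.as_tensor(image)
    if t.ndim == 2:
        t = t.reshape(1, 1, *t.shape)
    elif t.ndim == 3:
        t = t.reshape(t.shape[0], 1, t.shape[1], t.shape[2])
    return net(t)


# --------------------------------------------------------------- clustering
def kmeans(points: np.ndarray, k: int, rng: np.random.Generator,
           n_iter: int = 10) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Lloyd's k-means with k-means++ seeding on (M, D) points.

    Returns (labels, centers, per-iteration objectives). The squared-distance
    objective is non-increasing across iterations; empty clusters are re-seeded
    with the point farthest from its center.
    """
    m = points.shape[0]
    if k < 1:
        raise ValueError("k must be at least 1")
    if k > m:
        raise ValueError(f"k={k} exceeds number of points {m}")
    # k-means++ seeding
    centers = np.empty((k, points.shape[1]))
    centers[0] = points[rng.integers(m)]
    d2 = ((points - centers[0]) ** 2).sum(axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total <= 0:
            centers[j] = points[rng.integers(m)]
        else:
            centers[j] = points[rng.choice(m, p=d2 / total)]
        d2 = np.minimum(d2, ((points - centers[j]) ** 2).sum(axis=1))

    objectives: list[float] = []
    labels = np.zeros(m, dtype=np.int64)
    for _ in range(n_iter):
        dist = ((points[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        labels = dist.argmin(axis=1)
        objectives.append(float(dist[np.arange(m), labels].sum()))
        for j in range(k):
            mask = labels == j
            if mask.any():
                centers[j] = points[mask].mean(axis=0)
            else:
                worst = dist[np.arange(m), labels].argmax()
                centers[j] = points[worst]
    dist = ((points[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    labels = dist.argmin(axis=1)
    objectives.append(float(dist[np.arange(m), labels].sum()))
    return labels, centers, objectives


@dataclass
class ClusterState:
    """Per-view pseudo-labels and unit-norm cluster centers."""

    labels1: np.ndarray
    labels2: np.ndarray
    centers1: np.ndarray
    centers2: np.ndarray
    k: int


def cluster_views(z1: np.ndarray, z2: np.ndarray, k: int,
                  seed: int) -> ClusterState:
    """Independent k-means over the pooled pixels of each feature view.

    z1, z2: (M, D) detached per-pixel features. Centers are re-normalized to
    unit length on return.
    """
    if z1.shape[0] < k or z2.shape[0] < k:
        raise ValueError("fewer pixels than clusters")
    rng = np.random.default_rng(seed)
    labels1, c1, _ = kmeans(z1, k, rng)
    labels2, c2, _ = kmeans(z2, k, rng)
    c1 = c1 / np.maximum(np.linalg.norm(c1, axis=1, keepdims=True), 1e-12)
    c2 = c2 / np.maximum(np.linalg.norm(c2, axis=1, keepdims=True), 1e-12)
    return ClusterState(labels1, labels2, c1, c2, k)


def clust_loss(z: Tensor, labels: np.ndarray, centers: np.ndarray) -> Tensor:
    """Mean soft-assignment negative log-likelihood under cosine distance.

    loss_p = -log[ exp(-d(z_p, mu_{y_p})) / sum_l exp(-d(z_p, mu_l)) ],
    d = 1 - cosine similarity (z and mu unit-norm). Labels and centers are
    constants (stop-gradient).
    """
    k = centers.shape[0]
    if labels.min() < 0 or labels.max() >= k:
        raise IndexError("cluster label out of range")
    sim = z @ Tensor(centers.T)           # (M, K); d = 1 - sim
    logits = sim - 1.0                    # -d
    # stable log-sum-exp with a constant shift
    shift = Tensor(logits.data.max(axis=1, keepdims=True))
    lse = ((logits - shift).exp().sum(axis=1, keepdims=True)).log() + shift
    picked = (logits * Tensor(np.eye(k)[labels])).sum(axis=1, keepdims=True)
    return (lse - picked).mean()


def _flatten_pixels(z: Tensor) -> Tensor:
    """(N, D, H, W) -> (N*H*W, D)."""
    n, d, h, w = z.shape
    return z.transpose((0, 2, 3, 1)).reshape(n * h * w, d)


def semantic_loss(fused: Tensor | np.ndarray, net: SegmentationNet, k: int,
                  rng: np.random.Generator,
                  jitter: PhotometricJitter = PhotometricJitter(),
                  use_geometric: bool = True,
                  ) -> tuple[Tensor, float, float]:
    """Photometric-invariance / geometric-equivariance clustering loss.

    Builds two jittered views per image (view 2 optionally horizontally
    flipped and inverse-aligned after encoding), clusters each view's pooled
    pixel features, and returns (L_semantic tensor, L_within, L_cross) with
    L_semantic = L_within + L_cross, each averaged per pixel.
    """
    x = ag.as_tensor(fused)
    if x.ndim == 2:
        x = x.reshape(1, 1, *x.shape)
    elif x.ndim == 3:
        x = x.reshape(x.shape[0], 1, x.shape[1], x.shape[2])
    n = x.shape[0]
    if n < 1:
        raise ValueError("semantic loss needs a non-empty batch")

    views1, views2 = [], []
    geos = []
    for i in range(n):
        xi = x[i:i + 1]
        b1, c1, g1 = jitter.draw(rng)
        b2, c2, g2 = jitter.draw(rng)
        geo = {"hflip": bool(rng.integers(2))} if use_geometric else {}
        views1.append(_apply_photometric(xi, b1, c1, g1))
        views2.append(_geometric_tensor(_apply_photometric(xi, b2, c2, g2),
                                        geo))
        geos.append(geo)
    v1 = ag.concat(views1, axis=0)
    z1 = net(v1)
    z2_parts = []
    for i in range(n):
        z2i = net(views2[i])
        z2_parts.append(_inverse_geometric_tensor(z2i, geos[i]))
    z2 = ag.concat(z2_parts, axis=0)

    f1 = _flatten_pixels(z1)
    f2 = _flatten_pixels(z2)
    state = cluster_views(f1.data.copy(), f2.data.copy(), k,
                          seed=int(rng.integers(2 ** 31)))
    l_within = clust_loss(f1, state.labels1, state.centers1) \
        + clust_loss(f2, state.labels2, state.centers2)
    l_cross = clust_loss(f1, state.labels2, state.centers2) \
        + clust_loss(f2, state.labels1, state.centers1)
    total = l_within + l_cross
    return total, float(l_within.data), float(l_cross.data)
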