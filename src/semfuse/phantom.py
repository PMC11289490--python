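"""Seeded synthetic brain-like phantoms for two-modality fusion experiments.

Generates registered pairs in which each structure is visible predominantly
in one modality, emulating the contrast complementarity of CT/MRI brain
slices: modality A ("CT-like") carries a dense bright elliptical ring (skull)
and small hyper-intense foci (calcifications); modality B ("MRI-like")
carries spatially correlated interior texture (soft tissue) and larger
high-signal masses (lesions). A ground-truth region map is emitted alongside
the images so that downstream clustering behaviour can be sanity-checked.

Region labels: 0 background, 1 ring, 2 tissue, 3 focus (A), 4 mass (B).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import write_gray, write_labels

__all__ = ["PhantomSpec", "RegisteredPair", "generate_pair", "generate_dataset",
           "LABEL_BACKGROUND", "LABEL_RING", "LABEL_TISSUE", "LABEL_FOCUS",
           "LABEL_MASS"]

LABEL_BACKGROUND = 0
LABEL_RING = 1
LABEL_TISSUE = 2
LABEL_FOCUS = 3
LABEL_MASS = 4

_BACKGROUND_A = 0.05
_BACKGROUND_B = 0.05
_TISSUE_A = 0.25
_RING_A = 0.9
_RING_B = 0.2
_FOCUS_A = 0.95
_MASS_B = 0.9


class ConfigurationError(ValueError):
    """Invalid generator or training configuration."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one registered phantom pair.

    Sizes are pixels; noise_sd is the standard deviation of additive Gaussian
    noise in [0,1] intensity units; texture_scale_b is the correlation length
    of the modality-B soft-tissue texture.
    """

    height: int = 256
    width: int = 256
    n_foci_a: int = 3
    n_masses_b: int = 2
    texture_scale_b: float = 6.0
    ring_width: int = 8
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.height < 32 or self.width < 32:
            raise ConfigurationError("phantom size must be at least 32x32")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        if self.n_foci_a < 0 or self.n_masses_b < 0:
            raise ConfigurationError("feature counts must be non-negative")
        if self.ring_width < 1:
            raise ConfigurationError("ring_width must be at least 1 pixel")
        if self.texture_scale_b <= 0:
            raise ConfigurationError("texture_scale_b must be positive")


@dataclass
class RegisteredPair:
    """A co-registered two-modality phantom with its ground-truth region map."""

    image_a: np.ndarray
    image_b: np.ndarray
    region_map: np.ndarray

    def __post_init__(self):
        if not (self.image_a.shape == self.image_b.shape
                == self.region_map.shape):
            raise ValueError("pair members must share dimensions")


def _ellipse_mask(h: int, w: int, cy: float, cx: float,
                  ry: float, rx: float) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def _disc_mask(h: int, w: int, cy: float, cx: float, r: float) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r


def _place_discs(rng: np.random.Generator, n: int, interior: np.ndarray,
                 r_lo: float, r_hi: float, min_gap: float,
                 occupied: list[tuple[float, float, float]],
                 ) -> list[tuple[float, float, float]]:
    """Rejection-sample n non-overlapping discs inside the interior mask."""
    h, w = interior.shape
    ys, xs = np.nonzero(interior)
    placed: list[tuple[float, float, float]] = []
    attempts = 0
    while len(placed) < n:
        attempts += 1
        if attempts > 20000:
            raise ConfigurationError(
                "could not place requested features; reduce counts or radii")
        i = rng.integers(len(ys))
        cy, cx, r = float(ys[i]), float(xs[i]), float(rng.uniform(r_lo, r_hi))
        # keep the disc (plus a guard band) entirely inside the interior
        if (_disc_mask(h, w, cy, cx, r + 1) & ~interior).any():
            continue
        ok = True
        for oy, ox, orr in placed + occupied:
            if np.hypot(cy - oy, cx - ox) < r + orr + min_gap:
                ok = False
                break
        if ok:
            placed.append((cy, cx, r))
    return placed


def generate_pair(spec: PhantomSpec) -> RegisteredPair:
    """Generate one registered phantom pair. Deterministic in `spec`."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    ry_out = 0.44 * h * rng.uniform(0.95, 1.0)
    rx_out = 0.40 * w * rng.uniform(0.95, 1.0)
    outer = _ellipse_mask(h, w, cy, cx, ry_out, rx_out)
    inner = _ellipse_mask(h, w, cy, cx, ry_out - spec.ring_width,
                          rx_out - spec.ring_width)
    ring = outer & ~inner

    region = np.full((h, w), LABEL_BACKGROUND, dtype=np.int32)
    region[inner] = LABEL_TISSUE
    region[ring] = LABEL_RING

    # shrink interior so that features never touch the ring
    margin = _ellipse_mask(h, w, cy, cx, ry_out - spec.ring_width - 3,
                           rx_out - spec.ring_width - 3)

    r_scale = min(h, w) / 64.0
    masses = _place_discs(rng, spec.n_masses_b, margin,
                          3.0 * r_scale, 4.5 * r_scale,
                          min_gap=3.0, occupied=[])
    foci = _place_discs(rng, spec.n_foci_a, margin,
                        1.5 * r_scale, 2.5 * r_scale,
                        min_gap=3.0, occupied=masses)

    image_a = np.full((h, w), _BACKGROUND_A)
    image_a[inner] = _TISSUE_A
    image_a[ring] = _RING_A

    texture = rng.normal(size=(h, w))
    texture = ndimage.gaussian_filter(texture, sigma=spec.texture_scale_b)
    t_lo, t_hi = texture.min(), texture.max()
    if t_hi > t_lo:
        texture = 0.3 + 0.4 * (texture - t_lo) / (t_hi - t_lo)
    else:  # pragma: no cover - degenerate constant field
        texture = np.full((h, w), 0.5)

    image_b = np.full((h, w), _BACKGROUND_B)
    image_b[inner] = texture[inner]
    image_b[ring] = _RING_B

    for fy, fx, fr in foci:
        m = _disc_mask(h, w, fy, fx, fr)
        image_a[m] = _FOCUS_A
        region[m] = LABEL_FOCUS
    for my, mx, mr in masses:
        m = _disc_mask(h, w, my, mx, mr)
        image_b[m] = _MASS_B
        region[m] = LABEL_MASS

    if spec.noise_sd > 0:
        image_a = image_a + rng.normal(0.0, spec.noise_sd, size=(h, w))
        image_b = image_b + rng.normal(0.0, spec.noise_sd, size=(h, w))
    image_a = np.clip(image_a, 0.0, 1.0)
    image_b = np.clip(image_b, 0.0, 1.0)
    return RegisteredPair(image_a, image_b, region)


def count_regions(region_map: np.ndarray, label: int) -> int:
    """Number of connected components carrying `label` in a region map."""
    _, n = ndimage.label(region_map == label)
    return int(n)


def generate_dataset(n: int, spec: PhantomSpec,
                     out_dir: str | Path | None = None,
                     ) -> tuple[list[RegisteredPair], pd.DataFrame]:
    """Generate `n` pairs with per-pair seeds spec.seed + i.

    If `out_dir` is given, writes 16-bit grayscale PNGs `{id}_A.png` /
    `{id}_B.png`, an 8-bit region-map PNG, and `manifest.csv`.
    """
    if n < 1:
        raise ConfigurationError("dataset size must be at least 1")
    pairs: list[RegisteredPair] = []
    rows = []
    for i in range(n):
        pair_spec = replace(spec, seed=spec.seed + i)
        pair = generate_pair(pair_spec)
        pairs.append(pair)
        pid = f"phantom_{i:04d}"
        row = {"id": pid, "seed": pair_spec.seed,
               "path_a": f"{pid}_A.png", "path_b": f"{pid}_B.png",
               "path_map": f"{pid}_map.png"}
        if out_dir is not None:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            write_gray(pair.image_a, out / row["path_a"], bitdepth=16)
            write_gray(pair.image_b, out / row["path_b"], bitdepth=16)
            write_labels(pair.region_map, out / row["path_map"])
        rows.append(row)
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        manifest.to_csv(Path(out_dir) / "manifest.csv", index=False)
    return pairs, manifest


def manifest_checksum(out_dir: str | Path) -> str:
    """SHA-256 over the manifest and all files it lists (regression checks)."""
    out = Path(out_dir)
    h = hashlib.sha256()
    manifest = pd.read_csv(out / "manifest.csv")
    h.update(manifest.to_csv(index=False).encode())
    for _, row in manifest.iterrows():
        for col in ("path_a", "path_b", "path_map"):
            h.update((out / row[col]).read_bytes())
    return h.hexdigest()
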