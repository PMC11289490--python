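"""Grayscale image readers/writers for 8/16-bit PNG and TIFF.

Intensities are held in memory as float64 arrays in [0,1]; files store
bit-depth-quantized integers. Color (PET-like) inputs are converted to a
luminance channel on read; the chroma planes can be retained for YCbCr-style
color transfer back onto a fused luminance image.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = ["read_gray", "write_gray", "write_labels", "read_labels",
           "read_color_ycbcr", "recompose_color"]

_SUPPORTED = {".png", ".tif", ".tiff"}

# ITU-R BT.601 luma/chroma coefficients
_YR, _YG, _YB = 0.299, 0.587, 0.114


def _check_path(path: str | Path) -> Path:
    path = Path(path)
    if path.suffix.lower() not in _SUPPORTED:
        raise IOError(f"unsupported image format: {path}")
    return path


def _to_unit(arr: np.ndarray) -> np.ndarray:
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0
    if np.issubdtype(arr.dtype, np.floating):
        return np.clip(arr.astype(np.float64), 0.0, 1.0)
    raise IOError(f"unsupported pixel type {arr.dtype}")


def read_gray(path: str | Path) -> np.ndarray:
    """Read a single-channel (or color, via luminance) image into [0,1]."""
    path = _check_path(path)
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # pragma: no cover - backend specific
        raise IOError(f"could not read image {path}: {exc}") from exc
    if arr.size == 0:
        raise IOError(f"zero-sized image: {path}")
    img = _to_unit(arr)
    if img.ndim == 3:
        img = _YR * img[..., 0] + _YG * img[..., 1] + _YB * img[..., 2]
    if img.ndim != 2:
        raise IOError(f"expected 2-D image, got shape {arr.shape}: {path}")
    return img


def read_color_ycbcr(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a color image; return (luminance, chroma) with chroma (H,W,2)."""
    path = _check_path(path)
    arr = _to_unit(iio.imread(path))
    if arr.ndim != 3 or arr.shape[2] < 3:
        raise IOError(f"expected a color image: {path}")
    r, g, b = arr[..., 0], arr[..., 1], arr[..., 2]
    y = _YR * r + _YG * g + _YB * b
    cb = 0.5 + (b - y) / 1.772
    cr = 0.5 + (r - y) / 1.402
    return y, np.stack([cb, cr], axis=-1)


def recompose_color(y: np.ndarray, chroma: np.ndarray) -> np.ndarray:
    """Re-attach chroma planes to a (fused) luminance channel -> RGB in [0,1]."""
    cb = chroma[..., 0] - 0.5
    cr = chroma[..., 1] - 0.5
    r = y + 1.402 * cr
    b = y + 1.772 * cb
    g = (y - _YR * r - _YB * b) / _YG
    return np.clip(np.stack([r, g, b], axis=-1), 0.0, 1.0)


def write_gray(image: np.ndarray, path: str | Path, bitdepth: int = 16) -> Path:
    """Quantize an image in [0,1] to 8 or 16 bits and write it losslessly."""
    path = _check_path(path)
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("write_gray expects a 2-D image")
    if image.min() < 0.0 or image.max() > 1.0:
        raise ValueError("image intensities must lie in [0,1]")
    if bitdepth == 8:
        dtype, maxval = np.uint8, 255
    elif bitdepth == 16:
        dtype, maxval = np.uint16, 65535
    else:
        raise ValueError("bitdepth must be 8 or 16")
    quant = np.floor(image * maxval + 0.5).astype(dtype)  # round half up
    iio.imwrite(path, quant)
    return path


def write_labels(labels: np.ndarray, path: str | Path) -> Path:
    """Write an integer label field as an 8-bit PNG."""
    path = _check_path(path)
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() > 255:
        raise ValueError("label values must fit in 8 bits")
    iio.imwrite(path, labels.astype(np.uint8))
    return path


def read_labels(path: str | Path) -> np.ndarray:
    arr = iio.imread(_check_path(path))
    return arr.astype(np.int32)
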