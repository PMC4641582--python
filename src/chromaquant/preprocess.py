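"""Pre-processing of raw nucleus crops.

Raw micrograph crops (RGB or grayscale, 8- or 16-bit) are reduced to
8-bit single-channel images whose histogram spans the full dynamic range
[0, 255].  The processing order is crop -> grayscale -> contrast stretch.
"""

from __future__ import annotations

import warnings

import numpy as np
from PIL import Image

__all__ = [
    "read_image",
    "crop_center",
    "to_grayscale",
    "stretch_contrast",
    "preprocess_image",
]

# ITU-R BT.601 luminance weights for RGB -> gray.
_LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


def read_image(path) -> np.ndarray:
    """Read a PNG/TIFF image as a uint8 array (H, W) or (H, W, 3).

    16-bit inputs are rescaled to 8-bit (divide by 257) with a warning;
    palette and RGBA images are converted to RGB.
    """
    with Image.open(path) as im:
        if im.mode in ("I;16", "I;16B", "I;16L", "I"):
            arr = np.asarray(im, dtype=np.float64)
            warnings.warn(
                f"{path}: 16-bit input rescaled to 8-bit", stacklevel=2
            )
            arr = np.clip(arr / 257.0, 0, 255)
            return np.round(arr).astype(np.uint8)
        if im.mode not in ("L", "RGB"):
            im = im.convert("RGB")
        return np.asarray(im, dtype=np.uint8)


def _check_channels(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim == 2:
        return image
    if image.ndim == 3 and image.shape[2] in (1, 3):
        return image
    raise ValueError(
        f"expected a 1- or 3-channel image, got shape {image.shape}"
    )


def crop_center(image: np.ndarray, size: int) -> np.ndarray:
    """Return the centered ``size`` x ``size`` crop of ``image``.

    For an odd remainder the offset is floor-rounded, i.e. the crop sits
    one half-pixel toward the top-left of the exact midpoint.
    """
    image = _check_channels(image)
    h, w = image.shape[:2]
    if size > h or size > w:
        raise ValueError(
            f"crop size {size} exceeds image dimensions {h}x{w}"
        )
    top = (h - size) // 2
    left = (w - size) // 2
    return image[top : top + size, left : left + size].copy()


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Convert a 3-channel image to grayscale with BT.601 weights.

    Single-channel input is passed through unchanged.  Weighted sums are
    rounded half away from zero and clipped to [0, 255].
    """
    image = _check_channels(image)
    if image.ndim == 2:
        return image.astype(np.uint8, copy=True)
    if image.shape[2] == 1:
        return image[:, :, 0].astype(np.uint8, copy=True)
    luma = image.astype(np.float64) @ _LUMA_WEIGHTS
    # round half away from zero (values are non-negative here)
    return np.clip(np.floor(luma + 0.5), 0, 255).astype(np.uint8)


def stretch_contrast(
    image: np.ndarray,
    low_percentile: float = 0.0,
    high_percentile: float = 100.0,
) -> np.ndarray:
    """Linearly stretch the intensity histogram to span [0, 255].

    With the default percentiles the observed minimum maps to 0 and the
    observed maximum to 255.  Optional percentile clipping saturates the
    tails before stretching.  A constant image is returned unchanged.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("stretch_contrast expects a single-channel image")
    if image.size == 0:
        raise ValueError("empty image")
    lo = float(np.percentile(image, low_percentile))
    hi = float(np.percentile(image, high_percentile))
    if hi <= lo:
        return image.astype(np.uint8, copy=True)
    scaled = (image.astype(np.float64) - lo) * 255.0 / (hi - lo)
    return np.clip(np.floor(scaled + 0.5), 0, 255).astype(np.uint8)


def preprocess_image(
    image: np.ndarray,
    crop_size: int | None = None,
    stretch: bool = True,
    low_percentile: float = 0.0,
    high_percentile: float = 100.0,
) -> np.ndarray:
    """Full pre-processing chain: crop -> grayscale -> contrast stretch."""
    if crop_size is not None:
        image = crop_center(image, crop_size)
    image = to_grayscale(image)
    if stretch:
        image = stretch_contrast(image, low_percentile, high_percentile)
    return image
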