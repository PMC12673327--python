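"""Preprocessing: grayscale conversion, Otsu thresholding, binarization.

The classifier consumes binarized silhouettes, not raw photographs: global
Otsu thresholding separates the limb from the background and discards
illumination, skin tone and clothing texture, which is what makes the
method workable on small clinical samples.  Binarization happens at native
resolution; resizing to the square network input uses nearest-neighbor
interpolation so the image stays strictly two-valued.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image

__all__ = [
    "BinarizedImage",
    "to_grayscale",
    "otsu_threshold",
    "binarize",
    "prepare_input",
    "load_image",
    "preprocess_image",
]

# ITU-R BT.601 luminance weights for RGB -> gray.
_LUMA = (0.299, 0.587, 0.114)


@dataclass
class BinarizedImage:
    """Two-valued image with the threshold that produced it.

    Every pixel equals ``maxval`` iff its source grayscale value strictly
    exceeded ``threshold``; all other pixels are 0.
    """

    pixels: np.ndarray
    threshold: int
    maxval: int = 255
    source_id: str = ""

    def __post_init__(self) -> None:
        vals = np.unique(self.pixels)
        if not set(vals.tolist()) <= {0, self.maxval}:
            raise ValueError(f"pixels contain values {vals} outside {{0, {self.maxval}}}")


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Reduce an 8-bit image to single-channel using BT.601 weights.

    Single-channel input passes through unchanged; three-channel input is
    reduced by 0.299 R + 0.587 G + 0.114 B with round-half-up.
    """
    image = np.asarray(image)
    if image.ndim == 2:
        return image.astype(np.uint8, copy=False)
    if image.ndim == 3 and image.shape[2] == 3:
        gray = (
            _LUMA[0] * image[..., 0].astype(np.float64)
            + _LUMA[1] * image[..., 1]
            + _LUMA[2] * image[..., 2]
        )
        return np.floor(gray + 0.5).astype(np.uint8)
    raise ValueError(f"expected 1 or 3 channels, got shape {image.shape}")


def otsu_threshold(gray: np.ndarray) -> int:
    """Global threshold maximizing between-class variance (Otsu).

    Scans all 256 candidate thresholds t, splitting the histogram into the
    populations {<= t} and {> t}; among maximizers the smallest t wins.
    A constant image returns that constant (both classes are degenerate at
    every t, and t = value keeps the strict-inequality binarization all
    zeros).
    """
    gray = np.asarray(gray)
    if gray.size == 0:
        raise ValueError("cannot threshold an empty image")
    hist = np.bincount(gray.ravel().astype(np.int64), minlength=256).astype(np.float64)
    total = hist.sum()
    if np.count_nonzero(hist) == 1:
        return int(np.nonzero(hist)[0][0])
    omega = np.cumsum(hist) / total                      # P(value <= t)
    mu = np.cumsum(hist * np.arange(256)) / total        # partial mean
    mu_t = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_t * omega - mu) ** 2 / (omega * (1.0 - omega))
    sigma_b[~np.isfinite(sigma_b)] = 0.0
    return int(np.argmax(sigma_b))  # argmax returns the smallest maximizer


def binarize(gray: np.ndarray, thresh: int, maxval: int = 255, source_id: str = "") -> BinarizedImage:
    """Strict-inequality binarization: maxval where gray > thresh, else 0."""
    if not 0 <= thresh <= 255:
        raise ValueError(f"thresh {thresh} outside [0, 255]")
    if not 1 <= maxval <= 255:
        raise ValueError(f"maxval {maxval} outside [1, 255]")
    gray = np.asarray(gray)
    out = np.where(gray > thresh, np.uint8(maxval), np.uint8(0))
    return BinarizedImage(pixels=out, threshold=int(thresh), maxval=int(maxval), source_id=source_id)


def prepare_input(binary: BinarizedImage, side: int = 128) -> np.ndarray:
    """Resize to ``side``x``side`` (nearest-neighbor) and scale to {0, 1}.

    Returns a float32 array of shape ``(1, side, side)`` whose values are
    exactly 0.0 or 1.0.
    """
    if side <= 0 or side % 8 != 0:
        raise ValueError(f"side must be a positive multiple of 8, got {side}")
    px = binary.pixels
    h, w = px.shape
    rows = np.minimum((np.arange(side, dtype=np.int64) * h) // side, h - 1)
    cols = np.minimum((np.arange(side, dtype=np.int64) * w) // side, w - 1)
    resized = px[np.ix_(rows, cols)]
    out = (resized == binary.maxval).astype(np.float32)
    return out[np.newaxis, :, :]


def load_image(path) -> np.ndarray:
    """Read a PNG/JPEG as an 8-bit array (H, W) or (H, W, 3)."""
    with Image.open(path) as im:
        if im.mode == "L":
            return np.asarray(im)
        return np.asarray(im.convert("RGB"))


def preprocess_image(image: np.ndarray, side: int = 128, maxval: int = 255) -> np.ndarray:
    """Full pipeline: grayscale -> Otsu -> binarize -> network input."""
    gray = to_grayscale(image)
    t = otsu_threshold(gray)
    return prepare_input(binarize(gray, t, maxval), side)
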