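"""Grayscale image container, raster I/O and gray-level histograms.

A CT slice (or synthetic phantom) is held as a :class:`GrayImage`: a 2-D
integer grid with ``L`` gray levels, row-major, origin at the top-left,
0-based coordinates.  The histogram records per-level pixel counts ``n_i``
and the empirical probabilities ``p_i = n_i / n`` over all ``n = x * y``
pixels; every downstream threshold selector operates on the probabilities
only.

Supported raster formats are binary PGM (P5) and 8-bit single-channel PNG.
Binary masks travel as PNG/PGM images with values {0, 255}.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image as PILImage

from .errors import ImageFormatError

__all__ = [
    "GrayImage",
    "GrayHistogram",
    "load_gray_image",
    "save_gray_image",
    "load_mask",
    "save_mask",
    "compute_histogram",
]


@dataclass(frozen=True)
class GrayImage:
    """A 2-D single-channel image with ``levels`` gray levels.

    Parameters
    ----------
    pixels
        Integer array of shape ``(height, width)``; every value must lie in
        ``[0, levels - 1]``.  Values at or above ``levels`` are rejected, not
        clipped, so histogram probabilities stay exact.
    levels
        Number of gray levels ``L`` (256 for 8-bit data).
    """

    pixels: np.ndarray
    levels: int = 256

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ImageFormatError(f"expected a 2-D pixel grid, got ndim={px.ndim}")
        if not np.issubdtype(px.dtype, np.integer):
            raise ImageFormatError(f"pixel dtype must be integer, got {px.dtype}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ImageFormatError(f"image must be at least 1x1, got shape {px.shape}")
        if self.levels < 2:
            raise ImageFormatError(f"levels must be >= 2, got {self.levels}")
        if px.size and (px.min() < 0 or px.max() > self.levels - 1):
            raise ImageFormatError(
                f"intensities must lie in [0, {self.levels - 1}]; "
                f"found range [{px.min()}, {px.max()}]"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.pixels.size


@dataclass(frozen=True)
class GrayHistogram:
    """Per-level pixel counts and probabilities of a :class:`GrayImage`."""

    counts: np.ndarray
    probabilities: np.ndarray
    total: int

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        probs = np.asarray(self.probabilities, dtype=np.float64)
        if counts.shape != probs.shape or counts.ndim != 1:
            raise ValueError("counts and probabilities must be equal-length 1-D arrays")
        if counts.min(initial=0) < 0:
            raise ValueError("histogram counts must be non-negative")
        if counts.sum() != self.total:
            raise ValueError("histogram counts must sum to the pixel total")
        if self.total > 0 and abs(probs.sum() - 1.0) > 1e-12:
            raise ValueError("histogram probabilities must sum to 1")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "probabilities", probs)

    @property
    def levels(self) -> int:
        return self.counts.shape[0]

    @property
    def nonzero_levels(self) -> np.ndarray:
        """Gray levels with at least one pixel, ascending."""
        return np.flatnonzero(self.counts)


def compute_histogram(image: GrayImage) -> GrayHistogram:
    """Tally the gray-level histogram of ``image``.

    ``counts[i]`` is the number of pixels with intensity ``i`` and
    ``probabilities[i] = counts[i] / n`` with ``n`` the total pixel count.
    """
    counts = np.bincount(image.pixels.ravel(), minlength=image.levels).astype(np.int64)
    n = image.n_pixels
    return GrayHistogram(counts=counts, probabilities=counts / n, total=n)


def _open_raster(path: str | Path) -> PILImage.Image:
    try:
        return PILImage.open(path)
    except FileNotFoundError:
        raise
    except OSError as exc:  # unreadable / truncated / not a raster
        raise OSError(f"cannot read raster image {path!r}: {exc}") from exc


def load_gray_image(path: str | Path, levels: int = 256) -> GrayImage:
    """Load a single-channel 8-bit PGM or PNG raster as a :class:`GrayImage`.

    Multi-channel images (RGB/RGBA/palette) and bit depths other than 8 are
    rejected with an :class:`ImageFormatError` naming the offending property.
    """
    img = _open_raster(path)
    if img.mode in ("I", "I;16", "I;16B", "F"):
        raise ImageFormatError(
            f"{path}: bit depth is not 8 (PIL mode {img.mode!r}); only 8-bit "
            "single-channel rasters are supported"
        )
    if img.mode != "L":
        n_ch = len(img.getbands())
        raise ImageFormatError(
            f"{path}: expected 1 channel, got {n_ch} (PIL mode {img.mode!r})"
        )
    pixels = np.asarray(img, dtype=np.uint8)
    return GrayImage(pixels=pixels, levels=levels)


def save_gray_image(image: GrayImage, path: str | Path) -> None:
    """Write ``image`` as binary PGM (``.pgm``) or 8-bit grayscale PNG."""
    if image.levels > 256:
        raise ImageFormatError("only images with levels <= 256 can be written as 8-bit")
    PILImage.fromarray(image.pixels.astype(np.uint8), mode="L").save(path)


def load_mask(path: str | Path) -> np.ndarray:
    """Load a binary mask image; nonzero pixels are foreground."""
    img = _open_raster(path)
    if img.mode != "L":
        raise ImageFormatError(
            f"{path}: masks must be single-channel 8-bit (PIL mode {img.mode!r})"
        )
    return np.asarray(img, dtype=np.uint8) > 0


def save_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a boolean mask as an 8-bit image with values {0, 255}."""
    arr = np.where(np.asarray(mask, dtype=bool), 255, 0).astype(np.uint8)
    PILImage.fromarray(arr, mode="L").save(path)
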