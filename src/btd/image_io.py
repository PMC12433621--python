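"""Loading, normalisation, validation and saving of grayscale radiographs.

This module owns the raster conventions used across the package:

* origin at the top-left corner, 0-based ``(row, col)`` indexing;
* 4-neighbourhood adjacency for stencils and boundary extraction;
* intensities normalised to ``[0, 1]`` in the *bones-bright* polarity
  (the subtracted display in which bone appears brighter than tissue).

Integer inputs are divided by the full-scale maximum of their bit depth
rather than the per-image maximum, so the linear relation between pixel
intensity and X-ray dose is preserved.  Sensor-native bones-dark images
are handled by the explicit ``invert`` flag; no polarity auto-detection
is attempted.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import imageio.v3 as iio
import tifffile

from .exceptions import ImageRangeError, ImageReadError

__all__ = [
    "load_radiograph",
    "save_image",
    "load_mask",
    "save_mask",
    "validate_radiograph",
    "normalize_array",
]

#: minimum grid size on which the 5-point stencil is meaningful
MIN_SIDE = 3


def validate_radiograph(pixels: np.ndarray) -> np.ndarray:
    """Check radiograph invariants and return the array as float64.

    Requirements: a 2-D grid at least 3x3, finite, with every value in
    ``[0, 1]``.
    """
    arr = np.asarray(pixels, dtype=np.float64)
    if arr.ndim != 2:
        raise ImageReadError(f"expected a 2-D grid, got shape {arr.shape}")
    if arr.shape[0] < MIN_SIDE or arr.shape[1] < MIN_SIDE:
        raise ImageReadError(
            f"image must be at least {MIN_SIDE}x{MIN_SIDE}, got {arr.shape}"
        )
    if not np.all(np.isfinite(arr)):
        raise ImageReadError("image contains non-finite values")
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise ImageRangeError(
            f"pixel values outside [0, 1]: min={arr.min()}, max={arr.max()}"
        )
    return arr


def normalize_array(
    raw: np.ndarray, *, invert: bool = False, rescale: bool = False
) -> np.ndarray:
    """Normalise a raw decoded array to a valid radiograph in [0, 1].

    Integer dtypes are divided by their full-scale maximum (e.g. 255,
    65535); floating dtypes are clipped to [0, 1].  ``rescale`` switches
    to per-image min-max scaling, which discards the dose relationship
    and is therefore opt-in.  ``invert`` maps v -> 1 - v afterwards.
    """
    raw = np.asarray(raw)
    if raw.ndim == 3:
        # reducible multi-channel: all channels must agree
        if raw.shape[2] == 4:  # drop an alpha channel silently
            raw = raw[:, :, :3]
        if not np.all(raw == raw[:, :, :1]):
            raise ImageReadError("multi-channel image with unequal channels")
        raw = raw[:, :, 0]
    if raw.ndim != 2:
        raise ImageReadError(f"cannot interpret array of shape {raw.shape}")

    if np.issubdtype(raw.dtype, np.integer):
        scale = float(np.iinfo(raw.dtype).max)
        arr = raw.astype(np.float64) / scale
    else:
        arr = np.clip(raw.astype(np.float64), 0.0, 1.0)

    if rescale:
        lo, hi = arr.min(), arr.max()
        if hi > lo:
            arr = (arr - lo) / (hi - lo)
    if invert:
        arr = 1.0 - arr
    if arr.max() == arr.min():
        warnings.warn("image is constant; decomposition will find no bone signal")
    return validate_radiograph(arr)


def load_radiograph(
    path: str | Path, *, invert: bool = False, rescale: bool = False
) -> np.ndarray:
    """Load a single-channel radiograph from PNG/TIFF and normalise it.

    Parameters
    ----------
    path
        Image file; 8/16-bit integer PNG or TIFF, or 32-bit float TIFF.
    invert
        Apply v -> 1 - v for sensor-native bones-dark images.
    rescale
        Per-image min-max scaling instead of full-scale normalisation.
    """
    path = Path(path)
    try:
        raw = iio.imread(path)
    except Exception as exc:  # plugin backends raise heterogeneous types
        raise ImageReadError(f"cannot read image {path}: {exc}") from exc
    return normalize_array(raw, invert=invert, rescale=rescale)


def save_image(img: np.ndarray, path: str | Path, bit_depth: int | str = 16) -> None:
    """Save an image in [0, 1] as 8/16-bit integer or 32-bit float.

    Integer outputs quantise with round-half-up; float output (TIFF
    only) is lossless.  Values outside [0, 1] are rejected rather than
    clipped, so accidental range violations surface early.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.min() < 0.0 or img.max() > 1.0:
        raise ImageRangeError(
            f"refusing to save values outside [0, 1]: "
            f"min={img.min()}, max={img.max()}"
        )
    path = Path(path)
    if bit_depth == 8:
        out = np.floor(img * 255.0 + 0.5).astype(np.uint8)
        iio.imwrite(path, out)
    elif bit_depth == 16:
        out = np.floor(img * 65535.0 + 0.5).astype(np.uint16)
        iio.imwrite(path, out)
    elif bit_depth == "float":
        if path.suffix.lower() not in {".tif", ".tiff"}:
            raise ValueError("float output requires a .tif/.tiff path")
        tifffile.imwrite(path, img.astype(np.float64))
    else:
        raise ValueError(f"bit_depth must be 8, 16 or 'float', got {bit_depth!r}")


def load_mask(path: str | Path) -> np.ndarray:
    """Load a binary mask raster (nonzero = inside mask) as a bool grid."""
    try:
        raw = iio.imread(Path(path))
    except Exception as exc:  # plugin backends raise heterogeneous types
        raise ImageReadError(f"cannot read mask {path}: {exc}") from exc
    if raw.ndim == 3:
        raw = raw[:, :, 0]
    return np.asarray(raw) != 0


def save_mask(mask: np.ndarray, path: str | Path) -> None:
    """Save a boolean mask as an 8-bit raster (255 = inside)."""
    out = np.where(np.asarray(mask, dtype=bool), 255, 0).astype(np.uint8)
    iio.imwrite(Path(path), out)
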