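"""Bone-covering mask estimation, validation and boundary extraction.

The mask M is deliberately loose: it only has to *cover* every
bone-carrying pixel, not trace bone boundaries, because the tissue
estimate inside M is interpolated from values just outside it.  The
default recipe (Otsu threshold, morphological closing, hole filling,
small-component removal, generous dilation) over-covers by design.

The Dirichlet boundary ``∂M`` consists of the pixels *outside* M that
are 4-adjacent to M; their intensities supply the boundary condition
T = f for the Laplace solve.  Mask components that touch the image
border get their missing neighbours synthesised by edge replication,
so the boundary can carry coordinates one step outside the raster
(row -1 or H, col -1 or W) with values taken from the nearest edge
pixel of f.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import closing, dilation, disk, remove_small_objects

from .exceptions import EmptyMaskError, ShapeMismatchError

__all__ = [
    "MaskBoundary",
    "estimate_mask",
    "validate_user_mask",
    "extract_boundary",
]


@dataclass(frozen=True)
class MaskBoundary:
    """Dirichlet boundary of a bone mask.

    ``pixels`` is an (N, 2) integer array of (row, col) positions
    outside the mask that are 4-adjacent to it; positions may lie one
    step outside the raster when the mask touches the image border.
    ``values`` holds the corresponding intensities of f, edge-replicated
    where the position is off-raster.
    """

    pixels: np.ndarray
    values: np.ndarray

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.pixels)


def estimate_mask(
    f: np.ndarray,
    threshold: str | float = "otsu",
    close_radius: int = 3,
    dilate_radius: int = 5,
    min_area: int = 64,
    fill_holes: bool = True,
) -> np.ndarray:
    """Estimate a bone-covering mask by thresholding plus morphology.

    Steps, in order: binarise ``f >= threshold``; morphological closing
    with a disk of ``close_radius``; hole filling; removal of connected
    components smaller than ``min_area`` (8-adjacency); dilation with a
    disk of ``dilate_radius``.  The dilation is what guarantees the
    cover property without requiring boundary alignment.

    Raises
    ------
    EmptyMaskError
        If no pixel survives, i.e. no bone-like region was found.
    """
    f = np.asarray(f, dtype=np.float64)
    if threshold == "otsu":
        thr = float(threshold_otsu(f))
    else:
        thr = float(threshold)
    mask = f >= thr
    if close_radius > 0:
        mask = closing(mask, disk(close_radius))
    if fill_holes:
        mask = ndimage.binary_fill_holes(mask)
    if min_area > 0:
        # drop components strictly smaller than min_area
        mask = remove_small_objects(mask, max_size=min_area - 1, connectivity=2)
    if dilate_radius > 0:
        mask = dilation(mask, disk(dilate_radius))
    if not mask.any():
        raise EmptyMaskError(
            f"no bone-like region found (threshold {thr:.4g}, min_area {min_area})"
        )
    return mask


def validate_user_mask(mask: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Validate a user-supplied mask against the companion image.

    Any nonzero entry counts as inside.  A warning is emitted when the
    mask reaches the image border, because the Dirichlet data there is
    synthesised by edge replication rather than observed.
    """
    mask = np.asarray(mask)
    f = np.asarray(f)
    if mask.shape != f.shape:
        raise ShapeMismatchError(
            f"mask shape {mask.shape} does not match image shape {f.shape}"
        )
    mask = mask != 0
    if not mask.any():
        raise EmptyMaskError("user mask is empty")
    if mask[0, :].any() or mask[-1, :].any() or mask[:, 0].any() or mask[:, -1].any():
        warnings.warn(
            "mask touches the image border; boundary values there are "
            "edge-replicated from f"
        )
    return mask


_N4 = ((-1, 0), (1, 0), (0, -1), (0, 1))


def extract_boundary(mask: np.ndarray, f: np.ndarray) -> MaskBoundary:
    """Extract the Dirichlet boundary ∂M with its intensity values.

    The boundary is the set of positions outside M 4-adjacent to at
    least one mask pixel.  For mask pixels on the image border the
    missing outside neighbour is synthesised by edge replication of f,
    yielding off-raster coordinates whose value is f at the clipped
    position.
    """
    mask = np.asarray(mask, dtype=bool)
    f = np.asarray(f, dtype=np.float64)
    if mask.shape != f.shape:
        raise ShapeMismatchError("mask and image shapes differ")
    if not mask.any():
        raise EmptyMaskError("cannot extract the boundary of an empty mask")

    h, w = mask.shape
    padded = np.zeros((h + 2, w + 2), dtype=bool)
    padded[1:-1, 1:-1] = mask
    # neighbours of the mask under 4-adjacency, in padded coordinates
    neigh = np.zeros_like(padded)
    neigh[:-1, :] |= padded[1:, :]
    neigh[1:, :] |= padded[:-1, :]
    neigh[:, :-1] |= padded[:, 1:]
    neigh[:, 1:] |= padded[:, :-1]
    ring = neigh & ~padded
    rows, cols = np.nonzero(ring)
    rows = rows - 1  # back to image coordinates; may be -1 or h
    cols = cols - 1
    values = f[np.clip(rows, 0, h - 1), np.clip(cols, 0, w - 1)]
    pixels = np.stack([rows, cols], axis=1)
    return MaskBoundary(pixels=pixels, values=values)
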