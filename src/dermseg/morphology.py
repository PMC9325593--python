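"""Binary morphology for seed-mask cleanup.

All operations take and return boolean masks of unchanged shape and use
the infinite-plane convention that everything beyond the image frame is
background: erosion shrinks objects touching the border, dilation may
not grow past the frame, and closing remains extensive (result contains
the input) because it is evaluated on a zero-padded canvas and cropped
back.  Foreground connectivity is 8-connected everywhere; the dual
background connectivity (hole filling) is 4-connected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

#: 3x3 all-ones structure: 8-connectivity for foreground labelling.
EIGHT_CONNECTED = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class StructuringElement:
    """Binary footprint used by erosion/dilation.

    ``shape`` is "disk" or "square"; ``size`` is the disk radius or the
    square side, in pixels.
    """

    shape: str
    size: int
    footprint: np.ndarray = field(repr=False)


def disk_element(radius: int) -> StructuringElement:
    """Disk footprint: offsets (i, j) with i^2 + j^2 <= radius^2."""
    radius = int(radius)
    if radius < 1:
        raise ValueError(f"disk radius must be >= 1, got {radius}")
    offsets = np.arange(-radius, radius + 1)
    i, j = np.meshgrid(offsets, offsets, indexing="ij")
    footprint = (i ** 2 + j ** 2) <= radius ** 2
    return StructuringElement(shape="disk", size=radius, footprint=footprint)


def square_element(side: int) -> StructuringElement:
    """Square footprint of odd side length."""
    side = int(side)
    if side < 1 or side % 2 == 0:
        raise ValueError(f"square side must be odd and >= 1, got {side}")
    return StructuringElement(
        shape="square", size=side, footprint=np.ones((side, side), dtype=bool)
    )


def _as_mask(mask: np.ndarray) -> np.ndarray:
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D mask, got shape {arr.shape!r}")
    return arr.astype(bool)


def _pad_width(se: StructuringElement) -> int:
    return max(se.footprint.shape) // 2


def morph_open(mask: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Erosion followed by dilation; anti-extensive and idempotent."""
    m = _as_mask(mask)
    r = _pad_width(se)
    padded = np.pad(m, r, constant_values=False)
    opened = ndimage.binary_opening(padded, structure=se.footprint)
    return opened[r:-r, r:-r] if r else opened


def morph_close(mask: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Dilation followed by erosion; extensive and idempotent.

    Computed on a background-padded canvas so objects touching the
    frame are not clipped by the erosion pass.
    """
    m = _as_mask(mask)
    r = _pad_width(se)
    padded = np.pad(m, r, constant_values=False)
    closed = ndimage.binary_closing(padded, structure=se.footprint)
    return closed[r:-r, r:-r] if r else closed


def area_open(mask: np.ndarray, min_size: int) -> np.ndarray:
    """Drop 8-connected components with fewer than ``min_size`` pixels."""
    min_size = int(min_size)
    if min_size < 1:
        raise ValueError(f"min_size must be >= 1, got {min_size}")
    m = _as_mask(mask)
    labels, n = ndimage.label(m, structure=EIGHT_CONNECTED)
    if n == 0:
        return m.copy()
    counts = np.bincount(labels.ravel())
    keep = counts >= min_size
    keep[0] = False
    return keep[labels]


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Fill background regions not 4-connected to the image border."""
    m = _as_mask(mask)
    return ndimage.binary_fill_holes(m)  # default cross structure = 4-conn


def largest_component(mask: np.ndarray) -> np.ndarray:
    """Keep only the largest 8-connected component.

    Ties break to the component whose first pixel in raster order comes
    first (scipy labels components in raster order of first encounter,
    and argmax picks the first maximum).  An empty mask maps to itself.
    """
    m = _as_mask(mask)
    labels, n = ndimage.label(m, structure=EIGHT_CONNECTED)
    if n == 0:
        return np.zeros_like(m)
    counts = np.bincount(labels.ravel())[1:]
    keep = int(np.argmax(counts)) + 1
    return labels == keep


def component_sizes(mask: np.ndarray) -> list[int]:
    """Pixel counts of the 8-connected components (diagnostics)."""
    m = _as_mask(mask)
    labels, n = ndimage.label(m, structure=EIGHT_CONNECTED)
    if n == 0:
        return []
    return np.bincount(labels.ravel())[1:].tolist()
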