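"""Image and mask I/O (PNG/JPEG/TIFF via imageio)."""

from __future__ import annotations

import numpy as np
import imageio.v3 as iio


def load_image(path) -> np.ndarray:
    """Read an image as uint8; 16-bit inputs are rescaled to [0, 255].

    Gray inputs are returned 2-D; RGBA is reduced to RGB.
    """
    arr = iio.imread(path)
    if arr.dtype == np.uint16:
        arr = (arr.astype(float) / 257.0).round().astype(np.uint8)
    elif arr.dtype != np.uint8:
        arr = np.clip(np.rint(arr.astype(float)), 0, 255).astype(np.uint8)
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    return arr


def load_mask(path) -> np.ndarray:
    """Read a 0/255 PNG ground-truth mask as a boolean array."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[:, :, 0]
    return arr > 127


def save_mask(mask: np.ndarray, path) -> None:
    """Write a boolean mask as a 0/255 PNG."""
    iio.imwrite(path, (np.asarray(mask).astype(np.uint8) * 255))


def save_image(img: np.ndarray, path) -> None:
    iio.imwrite(path, np.asarray(img).astype(np.uint8))


def overlay_boundary(img: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Draw the mask boundary in green on a copy of the RGB image."""
    from scipy import ndimage

    rgb = np.asarray(img)
    if rgb.ndim == 2:
        rgb = np.stack([rgb] * 3, axis=-1)
    out = rgb.astype(np.uint8).copy()
    m = np.asarray(mask).astype(bool)
    boundary = m & ~ndimage.binary_erosion(m)
    out[boundary] = (0, 255, 0)
    return out
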