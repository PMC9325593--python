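"""Gray conversion and low-level filtering of dermoscopic images.

The pipeline works on 8-bit-range gray rasters (floats in [0, 255]).
Color input is collapsed with ITU-R BT.601 luma weights, then smoothed
with an explicitly constructed, unit-sum Gaussian kernel

    hg(n1, n2) = exp(-(n1^2 + n2^2) / (2 sigma^2)),
    h(n1, n2)  = hg(n1, n2) / sum(hg),

where (n1, n2) are integer offsets from the kernel center.  A median
filter is available for impulse-like noise (hairs, sensor speckle);
both filters use reflective border padding so image dimensions never
change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

#: ITU-R BT.601 luma weights for R, G, B.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """Collapse an H x W x 3 RGB raster to a gray raster via BT.601 luma.

    Returns a float array in [0, 255].  Raises ``ValueError`` for
    anything that is not a 3-channel raster.
    """
    arr = np.asarray(img)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(
            f"expected an H x W x 3 RGB image, got shape {arr.shape!r}"
        )
    weights = np.asarray(LUMA_WEIGHTS, dtype=float)
    return arr.astype(float) @ weights


def default_kernel_size(sigma: float) -> int:
    """Odd kernel size 2*ceil(3*sigma) + 1 capturing >99% of the mass."""
    return 2 * math.ceil(3.0 * float(sigma)) + 1


@dataclass(frozen=True)
class GaussianKernel:
    """Normalized isotropic Gaussian filter weights.

    Attributes
    ----------
    weights : (size, size) float array summing to 1, maximal at center.
    sigma : standard deviation in pixels.
    size : odd side length of the square support.
    """

    weights: np.ndarray = field(repr=False)
    sigma: float
    size: int


def gaussian_kernel(sigma: float, size: int | None = None) -> GaussianKernel:
    """Build the unit-sum Gaussian kernel for the given sigma.

    ``size`` must be odd; when omitted it defaults to
    ``2*ceil(3*sigma) + 1``.
    """
    sigma = float(sigma)
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    if size is None:
        size = default_kernel_size(sigma)
    size = int(size)
    if size < 1 or size % 2 == 0:
        raise ValueError(f"kernel size must be odd and >= 1, got {size}")
    offsets = np.arange(size) - size // 2
    n1, n2 = np.meshgrid(offsets, offsets, indexing="ij")
    hg = np.exp(-(n1 ** 2 + n2 ** 2) / (2.0 * sigma ** 2))
    weights = hg / hg.sum()
    return GaussianKernel(weights=weights, sigma=sigma, size=size)


def smooth(img: np.ndarray, kernel: GaussianKernel) -> np.ndarray:
    """Convolve a gray image with a Gaussian kernel (reflective borders).

    The isotropic Gaussian factorizes into two 1-D passes, so the
    convolution runs in O(K) per pixel instead of O(K^2).  Output has
    the same shape as the input, and its values stay inside the input
    range because the kernel is a convex combination.
    """
    arr = np.asarray(img, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D gray image, got shape {arr.shape!r}")
    size = kernel.size
    if size > arr.shape[0] or size > arr.shape[1]:
        raise ValueError(
            f"kernel {size}x{size} larger than image {arr.shape}"
        )
    offsets = np.arange(size) - size // 2
    g1 = np.exp(-(offsets ** 2) / (2.0 * kernel.sigma ** 2))
    g1 = g1 / g1.sum()
    out = ndimage.convolve1d(arr, g1, axis=0, mode="reflect")
    return ndimage.convolve1d(out, g1, axis=1, mode="reflect")


def median_filter(img: np.ndarray, window: int = 5) -> np.ndarray:
    """Window x window median with reflective border padding.

    Preserves edges while removing impulse noise; never introduces a
    value absent from the input.
    """
    window = int(window)
    if window < 1 or window % 2 == 0:
        raise ValueError(f"median window must be odd and >= 1, got {window}")
    arr = np.asarray(img)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D gray image, got shape {arr.shape!r}")
    return ndimage.median_filter(arr, size=window, mode="reflect")
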