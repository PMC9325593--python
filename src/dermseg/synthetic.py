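"""Dermoscopy phantom generator with exact ground truth.

Produces images that mimic the character of dermoscopic acquisitions: a
roughly elliptical pigmented lesion darker than the surrounding skin,
overlaid with the artifact classes that plague real dermoscopy — dark
hair strokes, saturated specular highlights, a low-frequency
illumination (shadow) gradient, and additive pixel noise.  The ground
truth mask is the rasterized lesion region *before* any artifact is
applied, so every downstream stage can be scored exactly.

Everything is driven by one integer seed; a fixed seed reproduces the
image byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from skimage import draw

from .morphology import fill_holes, largest_component

DEFAULT_IMAGE_SIZE = (226, 276)


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one phantom.

    Geometry: an ellipse with semi-axes ``lesion_axes`` (pixels),
    rotated by ``lesion_rotation`` radians, centered at
    ``lesion_center`` (image center when None), with its radius
    modulated by low-order harmonics of relative amplitude
    ``irregularity``.

    Photometry: skin base color ``skin_rgb``; the lesion is darker by
    ``contrast`` intensity units per channel.  ``shadow_amplitude`` is
    the peak deviation of a linear illumination ramp; hairs are dark
    curved strokes; specular highlights are saturated discs of radius
    1-3 px; ``noise_sigma`` is the std of additive Gaussian noise.
    """

    image_size: tuple[int, int] = DEFAULT_IMAGE_SIZE
    lesion_center: tuple[float, float] | None = None
    lesion_axes: tuple[float, float] = (40.0, 55.0)
    lesion_rotation: float = 0.4
    irregularity: float = 0.08
    skin_rgb: tuple[int, int, int] = (196, 168, 148)
    shadow_amplitude: float = 10.0
    n_hairs: int = 10
    hair_intensity: float = 45.0
    n_specular: int = 8
    noise_sigma: float = 5.0
    contrast: float = 70.0
    seed: int = 0


@dataclass(frozen=True)
class Phantom:
    """A generated image with its exact lesion ground truth."""

    image: np.ndarray = field(repr=False)
    truth_mask: np.ndarray = field(repr=False)
    spec: PhantomSpec


def _lesion_polygon(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Perturbed-ellipse boundary as a (720, 2) (row, col) polygon."""
    h, w = spec.image_size
    center = spec.lesion_center or (h / 2.0, w / 2.0)
    a, b = spec.lesion_axes
    t = np.linspace(0.0, 2 * np.pi, 720, endpoint=False)
    # low-order radial harmonics; |sum of coefficients| bounded by 1 so the
    # radial scale stays within 1 +- irregularity and the region stays simple
    orders = np.arange(2, 6)
    coef = rng.uniform(-1.0, 1.0, size=orders.size)
    norm = np.sum(np.abs(coef))
    if norm > 0:
        coef = coef / norm
    phases = rng.uniform(0.0, 2 * np.pi, size=orders.size)
    scale = 1.0 + spec.irregularity * np.sum(
        coef[:, None] * np.cos(orders[:, None] * t[None, :] + phases[:, None]),
        axis=0,
    )
    cr, sr = np.cos(spec.lesion_rotation), np.sin(spec.lesion_rotation)
    y = a * np.cos(t) * scale
    x = b * np.sin(t) * scale
    rows = center[0] + cr * y - sr * x
    cols = center[1] + sr * y + cr * x
    return np.column_stack([rows, cols])


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Render one phantom deterministically from its spec."""
    h, w = spec.image_size
    if min(spec.lesion_axes) <= 0:
        raise ValueError("lesion axes must be positive")
    rng = np.random.default_rng(spec.seed)

    poly = _lesion_polygon(spec, rng)
    margin = 2.0
    if (
        poly[:, 0].min() < margin
        or poly[:, 1].min() < margin
        or poly[:, 0].max() > h - 1 - margin
        or poly[:, 1].max() > w - 1 - margin
    ):
        raise ValueError("lesion does not fit inside the image frame")

    truth = np.zeros((h, w), dtype=bool)
    rr, cc = draw.polygon(poly[:, 0], poly[:, 1], shape=(h, w))
    truth[rr, cc] = True
    truth = largest_component(fill_holes(truth))

    img = np.empty((h, w, 3), dtype=float)
    img[:] = np.asarray(spec.skin_rgb, dtype=float)

    # illumination / shadow: zero-mean linear ramp in a random direction
    if spec.shadow_amplitude > 0:
        theta = rng.uniform(0.0, 2 * np.pi)
        rows, cols = np.mgrid[0:h, 0:w]
        ramp = (rows - h / 2) * np.cos(theta) + (cols - w / 2) * np.sin(theta)
        ramp = ramp / max(np.abs(ramp).max(), 1.0) * spec.shadow_amplitude
        img += ramp[:, :, None]

    img[truth] -= spec.contrast

    _draw_hairs(img, spec, rng)
    _draw_specular(img, spec, rng)

    if spec.noise_sigma > 0:
        img += rng.normal(0.0, spec.noise_sigma, size=img.shape)

    image = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return Phantom(image=image, truth_mask=truth, spec=spec)


def _draw_hairs(img: np.ndarray, spec: PhantomSpec, rng: np.random.Generator) -> None:
    """Dark curved polylines, 2-4 px wide, drawn across the frame."""
    h, w = spec.image_size
    for _ in range(spec.n_hairs):
        n_seg = rng.integers(3, 6)
        start = np.array([rng.uniform(0, h - 1), rng.uniform(0, w - 1)])
        heading = rng.uniform(0.0, 2 * np.pi)
        length = rng.uniform(0.25, 0.7) * min(h, w)
        pts = [start]
        for _ in range(n_seg):
            heading += rng.uniform(-0.5, 0.5)  # gentle curvature
            step = length / n_seg
            pts.append(
                pts[-1] + step * np.array([np.sin(heading), np.cos(heading)])
            )
        width = int(rng.integers(2, 4))  # strokes come out 2-4 px wide
        value = spec.hair_intensity + rng.uniform(-10, 10)
        hair = np.zeros((h, w), dtype=bool)
        for p, q in zip(pts[:-1], pts[1:]):
            p = np.clip(p, 0, [h - 1, w - 1])
            q = np.clip(q, 0, [h - 1, w - 1])
            rr, cc = draw.line(
                int(round(p[0])), int(round(p[1])),
                int(round(q[0])), int(round(q[1])),
            )
            hair[rr, cc] = True
        from scipy import ndimage

        hair = ndimage.binary_dilation(hair, structure=np.ones((width, width)))
        img[hair] = value


def _draw_specular(
    img: np.ndarray, spec: PhantomSpec, rng: np.random.Generator
) -> None:
    """Saturated circular highlights of radius 1-3 px."""
    h, w = spec.image_size
    for _ in range(spec.n_specular):
        r0 = rng.uniform(3, h - 4)
        c0 = rng.uniform(3, w - 4)
        radius = rng.integers(1, 4)
        rr, cc = draw.disk((r0, c0), radius, shape=(h, w))
        img[rr, cc] = 255.0


def generate_suite(
    n: int,
    base_spec: PhantomSpec | None = None,
    seed: int = 0,
    axes_range: tuple[float, float] = (20.0, 60.0),
    contrast_range: tuple[float, float] = (40.0, 100.0),
    hairs_range: tuple[int, int] = (0, 30),
    noise_range: tuple[float, float] = (0.0, 8.0),
) -> list[Phantom]:
    """Generate ``n`` phantoms with randomized geometry and artifacts.

    Per-phantom seeds are ``seed + index``, so extending a suite never
    reshuffles earlier members.  Lesion semi-axes, contrast, hair count
    and noise level are drawn uniformly from the given ranges; centers
    jitter around the image middle and rotations are uniform.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    base = base_spec or PhantomSpec()
    h, w = base.image_size
    phantoms = []
    for idx in range(n):
        sub_seed = int(seed) + idx
        rng = np.random.default_rng(sub_seed)
        axes = tuple(np.sort(rng.uniform(*axes_range, size=2))[::-1])
        max_axis = axes[0] * (1 + base.irregularity) + 4
        center = (
            float(np.clip(h / 2 + rng.uniform(-15, 15), max_axis, h - 1 - max_axis)),
            float(np.clip(w / 2 + rng.uniform(-15, 15), max_axis, w - 1 - max_axis)),
        )
        spec = replace(
            base,
            lesion_center=center,
            lesion_axes=(float(axes[1]), float(axes[0])),
            lesion_rotation=float(rng.uniform(0.0, np.pi)),
            contrast=float(rng.uniform(*contrast_range)),
            n_hairs=int(rng.integers(hairs_range[0], hairs_range[1] + 1)),
            noise_sigma=float(rng.uniform(*noise_range)),
            n_specular=int(rng.integers(0, 13)),
            seed=sub_seed,
        )
        phantoms.append(generate_phantom(spec))
    return phantoms
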