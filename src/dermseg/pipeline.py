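"""End-to-end lesion segmentation.

The procedure has two halves.  The seed half produces a lesion mask
without any human input: gray conversion, Gaussian smoothing,
maximum-entropy thresholding, a small median (majority) filter on the
binary mask, area opening, disk opening/closing, and largest-component
selection.  The refinement half turns that mask into the final
segmentation: its boundary initializes a greedy snake which locks onto
the image gradient, the converged contour is rasterized, lightly
opened/closed to remove rasterization jaggies, holes are filled, and
the largest component is kept.  The whole chain is deterministic.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from . import morphology as morph
from .exceptions import DegenerateImageError, SeedSelectionError
from .preprocess import gaussian_kernel, median_filter, smooth, to_grayscale
from .snake import (
    Contour,
    SnakeParams,
    contour_to_mask,
    evolve,
    external_energy_field,
    init_contour_from_mask,
)
from .threshold import (
    DARK_FOREGROUND,
    ThresholdResult,
    binarize,
    max_entropy_threshold,
    normalized_histogram,
)

logger = logging.getLogger(__name__)

OPEN_THEN_CLOSE = "open_then_close"
CLOSE_THEN_OPEN = "close_then_open"


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, with working defaults.

    ``median_target`` selects where the median filter acts: on the raw
    gray image before smoothing and thresholding ("gray", the default)
    or on the thresholded binary mask ("mask", a majority vote at the
    listed step-order position).  The default window of 9 px is sized
    to suppress the artifacts that poison a histogram threshold —
    hair strokes up to ~4 px wide and specular discs up to ~3 px
    radius — while leaving lesion-scale structure intact; entropy
    thresholds inflate the entropy of near-empty classes, so dark hair
    tails and bright highlight tails must be removed *before* the
    histogram is formed, not after.
    """

    gaussian_sigma: float = 2.0
    gaussian_size: int | None = None  # auto: 2*ceil(3 sigma)+1
    median_window: int = 9
    median_target: str = "gray"  # "gray" | "mask"
    clip_percentile: float = 1.0  # trim histogram tails before thresholding
    area_open_min_size: int = 100
    open_radius: int = 9
    close_radius: int = 25
    morph_order: str = OPEN_THEN_CLOSE
    threshold_polarity: str = DARK_FOREGROUND
    refine_radius: int = 3
    snake_alpha: float = 0.02
    snake_beta: float = 0.01
    snake_n_points: int = 100
    snake_max_iterations: int = 500
    snake_neighborhood: int = 3
    snake_field_sigma: float = 2.0

    def snake_params(self) -> SnakeParams:
        return SnakeParams(
            alpha=self.snake_alpha,
            beta=self.snake_beta,
            n_points=self.snake_n_points,
            max_iterations=self.snake_max_iterations,
            neighborhood=self.snake_neighborhood,
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class SegmentationResult:
    """Everything the pipeline produced for one image."""

    final_mask: np.ndarray = field(repr=False)
    seed_mask: np.ndarray = field(repr=False)
    contour: Contour
    threshold: ThresholdResult
    intermediates: dict = field(default_factory=dict, repr=False)
    timings: dict = field(default_factory=dict)
    snake_converged: bool = True


def _to_gray(img: np.ndarray) -> np.ndarray:
    arr = np.asarray(img)
    if arr.ndim == 3:
        return to_grayscale(arr)
    if arr.ndim == 2:
        return arr.astype(float)
    raise ValueError(f"expected a 2-D or 3-channel image, got shape {arr.shape!r}")


def select_seed_mask(
    img: np.ndarray,
    cfg: PipelineConfig | None = None,
    keep_intermediates: bool = False,
):
    """Automatic seed mask: smoothing, entropy threshold, morphology.

    Returns ``(mask, threshold_result)`` — or, with
    ``keep_intermediates``, ``(mask, threshold_result, stages)`` where
    ``stages`` maps stage names to intermediate arrays.  Raises
    :class:`SeedSelectionError` when no usable foreground survives.
    """
    cfg = cfg or PipelineConfig()
    stages: dict = {}
    gray = _to_gray(img)
    if cfg.median_target == "gray":
        gray = median_filter(gray, cfg.median_window)
    smoothed = smooth(gray, gaussian_kernel(cfg.gaussian_sigma, cfg.gaussian_size))
    stages["smoothed"] = smoothed

    # entropy thresholds inflate near-empty classes spread over many
    # levels, so bound the histogram support at the extreme quantiles
    if cfg.clip_percentile > 0:
        lo, hi = np.percentile(
            smoothed, [cfg.clip_percentile, 100.0 - cfg.clip_percentile]
        )
        thresh_input = np.clip(smoothed, lo, hi)
    else:
        thresh_input = smoothed

    hist = normalized_histogram(thresh_input)
    try:
        tres = max_entropy_threshold(hist, polarity=cfg.threshold_polarity)
    except DegenerateImageError as exc:
        raise SeedSelectionError(
            f"degenerate image: {exc}", threshold=None
        ) from exc
    mask = binarize(thresh_input, tres)
    stages["binary"] = mask

    if cfg.median_target == "mask":
        # median of a {0, 255} raster == majority vote on the binary mask
        mask = median_filter(mask.astype(np.uint8) * 255, cfg.median_window) > 127
    stages["median"] = mask

    sizes_before = morph.component_sizes(mask)
    mask = morph.area_open(mask, cfg.area_open_min_size) if mask.any() else mask
    stages["area_open"] = mask

    se_open = morph.disk_element(cfg.open_radius)
    se_close = morph.disk_element(cfg.close_radius)
    if cfg.morph_order == OPEN_THEN_CLOSE:
        mask = morph.morph_close(morph.morph_open(mask, se_open), se_close)
    elif cfg.morph_order == CLOSE_THEN_OPEN:
        mask = morph.morph_open(morph.morph_close(mask, se_close), se_open)
    else:
        raise ValueError(f"unknown morph_order {cfg.morph_order!r}")
    stages["opened_closed"] = mask

    seed = morph.largest_component(mask)
    stages["seed"] = seed
    if not seed.any():
        raise SeedSelectionError(
            "seed selection produced an empty mask",
            threshold=tres.threshold,
            component_sizes=sizes_before,
        )
    if keep_intermediates:
        return seed, tres, stages
    return seed, tres


def segment_lesion(
    img: np.ndarray,
    cfg: PipelineConfig | None = None,
    keep_intermediates: bool = False,
) -> SegmentationResult:
    """Full segmentation: seed mask, snake refinement, mask cleanup."""
    cfg = cfg or PipelineConfig()
    timings: dict = {}

    t0 = time.perf_counter()
    seed, tres, stages = select_seed_mask(img, cfg, keep_intermediates=True)
    timings["seed"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    contour0 = init_contour_from_mask(seed, cfg.snake_n_points)
    gray = _to_gray(img)
    if cfg.median_target == "gray":
        # the snake should track the lesion edge, not hair/highlight edges
        gray = median_filter(gray, cfg.median_window)
    field_ = external_energy_field(gray, sigma=cfg.snake_field_sigma)
    result = evolve(contour0, field_, cfg.snake_params())
    timings["snake"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    raw = contour_to_mask(result.contour, seed.shape)
    stages["snake_mask"] = raw
    se = morph.disk_element(cfg.refine_radius)
    refined = morph.morph_close(morph.morph_open(raw, se), se)
    refined = morph.fill_holes(refined)
    final = morph.largest_component(refined)
    timings["refine"] = time.perf_counter() - t0
    stages["final"] = final

    for name, dt in timings.items():
        logger.info("stage %-8s %.3fs", name, dt)

    return SegmentationResult(
        final_mask=final,
        seed_mask=seed,
        contour=result.contour,
        threshold=tres,
        intermediates=stages if keep_intermediates else {},
        timings=timings,
        snake_converged=result.converged,
    )
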