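"""Maximum-entropy (Kapur) threshold selection and binarization.

The gray image is reduced to a normalized 256-bin histogram h(i).  For a
candidate threshold t the pixels split into a "black" class (i <= t) and
a "white" class (i > t); each class gets the Shannon entropy of its
renormalized intensity distribution,

    H_B(t) = - sum_{i<=t} p_i ln p_i,   p_i = h(i) / sum_{j<=t} h(j),
    H_W(t) = - sum_{i>t}  q_i ln q_i,   q_i = h(i) / sum_{j>t}  h(j),

with the conventions 0 ln 0 = 0 and empty-class entropy = 0.  The
selected threshold maximizes H_B(t) + H_W(t) over all t for which both
classes are occupied; ties break to the smallest t so the result is
deterministic.  Natural logarithms are used throughout (the argmax is
base-invariant).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DegenerateImageError

N_LEVELS = 256

DARK_FOREGROUND = "dark_foreground"
BRIGHT_FOREGROUND = "bright_foreground"


def quantize(img: np.ndarray) -> np.ndarray:
    """Round a gray image to integer levels clipped to 0..255."""
    return np.clip(np.rint(np.asarray(img, dtype=float)), 0, 255).astype(np.int64)


def normalized_histogram(img: np.ndarray) -> np.ndarray:
    """256-bin normalized intensity histogram h(i), sum(h) == 1."""
    arr = np.asarray(img)
    if arr.size == 0:
        raise ValueError("cannot build a histogram from an empty image")
    levels = quantize(arr)
    counts = np.bincount(levels.ravel(), minlength=N_LEVELS)
    return counts / counts.sum()


def _entropy(p: np.ndarray) -> float:
    """Shannon entropy (nats) of a sub-distribution; 0 log 0 := 0."""
    p = p[p > 0]
    if p.size == 0:
        return 0.0
    return float(-np.sum(p * np.log(p)))


def class_entropies(hist: np.ndarray, t: int) -> tuple[float, float]:
    """Entropies (H_black, H_white) of the two classes split at t.

    black = levels i <= t, white = levels i > t.  An empty class has
    entropy 0 by convention (such t are excluded from the argmax by
    :func:`max_entropy_threshold`).
    """
    hist = np.asarray(hist, dtype=float)
    if not 0 <= t <= N_LEVELS - 1:
        raise ValueError(f"threshold must lie in 0..255, got {t}")
    # sums run over occupied levels only: splits at unoccupied levels
    # then yield bit-identical entropies, so argmax tie-breaking is exact
    low = hist[: t + 1]
    high = hist[t + 1:]
    low = low[low > 0]
    high = high[high > 0]
    h_black = _entropy(low / low.sum()) if low.size else 0.0
    h_white = _entropy(high / high.sum()) if high.size else 0.0
    return h_black, h_white


@dataclass(frozen=True)
class ThresholdResult:
    """Selected threshold plus the full entropy curve for inspection.

    ``total_entropy_curve[t]`` holds H_B(t) + H_W(t); entries where one
    class is empty are 0 and flagged inadmissible.
    """

    threshold: int
    total_entropy_curve: np.ndarray = field(repr=False)
    admissible: np.ndarray = field(repr=False)
    polarity: str = DARK_FOREGROUND


def max_entropy_threshold(
    hist: np.ndarray, polarity: str = DARK_FOREGROUND
) -> ThresholdResult:
    """Select T = argmax_t [H_B(t) + H_W(t)], smallest t on ties.

    Raises :class:`DegenerateImageError` when fewer than two gray levels
    are occupied (no split can separate two populations).
    """
    hist = np.asarray(hist, dtype=float)
    if polarity not in (DARK_FOREGROUND, BRIGHT_FOREGROUND):
        raise ValueError(f"unknown polarity {polarity!r}")
    if np.count_nonzero(hist) < 2:
        raise DegenerateImageError(
            "histogram has fewer than two occupied levels; no threshold exists"
        )
    cum = np.cumsum(hist)
    total = cum[-1]
    curve = np.zeros(N_LEVELS)
    admissible = np.zeros(N_LEVELS, dtype=bool)
    for t in range(N_LEVELS):
        if cum[t] > 0 and total - cum[t] > 0:
            admissible[t] = True
            h_b, h_w = class_entropies(hist, t)
            curve[t] = h_b + h_w
    masked = np.where(admissible, curve, -np.inf)
    threshold = int(np.argmax(masked))  # argmax returns first max: smallest t
    return ThresholdResult(
        threshold=threshold,
        total_entropy_curve=curve,
        admissible=admissible,
        polarity=polarity,
    )


def binarize(img: np.ndarray, result: ThresholdResult) -> np.ndarray:
    """Apply a selected threshold, honoring its foreground polarity.

    ``dark_foreground`` (the dermoscopy default: lesions are darker than
    skin) marks pixels <= T as foreground; ``bright_foreground`` marks
    pixels > T.
    """
    levels = quantize(img)
    if result.polarity == DARK_FOREGROUND:
        return levels <= result.threshold
    return levels > result.threshold


def entropy_curve_table(result: ThresholdResult, hist: np.ndarray) -> "np.ndarray":
    """(256, 4) array of (t, H_B, H_W, total) rows for CSV debugging."""
    rows = np.zeros((N_LEVELS, 4))
    for t in range(N_LEVELS):
        h_b, h_w = class_entropies(hist, t)
        rows[t] = (t, h_b, h_w, result.total_entropy_curve[t])
    return rows
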