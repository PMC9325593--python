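"""Segmentation overlap evaluation: Jaccard (P) and Dice (DSC).

With ground truth A and detection R,

    P(R, A)  = |A n R| / |A u R|          (Jaccard region coincidence)
    DSC(A,R) = 2 |A n R| / (|A| + |R|)    (Dice similarity coefficient)

Both live in [0, 1], are symmetric, and are linked by the identity
DSC = 2 P / (1 + P), so DSC >= P always.  Two empty masks score 1.0 (a
correctly empty prediction on a lesion-free image is a perfect
answer); a warning is emitted because the ratio is formally 0/0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class OverlapCounts:
    """Pixel counts underlying the overlap scores."""

    intersection_px: int
    union_px: int
    a_px: int
    r_px: int


@dataclass(frozen=True)
class PairScore:
    """Scores of one (prediction, truth) mask pair."""

    image_id: str
    image_size: tuple[int, int]
    counts: OverlapCounts
    jaccard_p: float
    dice: float


def overlap_counts(a: np.ndarray, r: np.ndarray) -> OverlapCounts:
    """Count intersection/union pixels of truth mask ``a`` vs detection ``r``."""
    a = np.asarray(a).astype(bool)
    r = np.asarray(r).astype(bool)
    if a.shape != r.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {r.shape}")
    inter = int(np.count_nonzero(a & r))
    a_px = int(np.count_nonzero(a))
    r_px = int(np.count_nonzero(r))
    return OverlapCounts(
        intersection_px=inter,
        union_px=a_px + r_px - inter,
        a_px=a_px,
        r_px=r_px,
    )


def jaccard(counts: OverlapCounts) -> float:
    """P = |A n R| / |A u R|; 1.0 (with a warning) when both masks are empty."""
    if counts.union_px == 0:
        warnings.warn(
            "both masks empty; Jaccard defined as 1.0 (vacuous agreement)",
            stacklevel=2,
        )
        return 1.0
    return counts.intersection_px / counts.union_px


def dice(counts: OverlapCounts) -> float:
    """DSC = 2 |A n R| / (|A| + |R|); 1.0 (with a warning) when both empty."""
    denom = counts.a_px + counts.r_px
    if denom == 0:
        warnings.warn(
            "both masks empty; Dice defined as 1.0 (vacuous agreement)",
            stacklevel=2,
        )
        return 1.0
    return 2.0 * counts.intersection_px / denom


def score_pair(pred: np.ndarray, truth: np.ndarray, image_id: str = "") -> PairScore:
    """Score one prediction against its ground truth."""
    counts = overlap_counts(truth, pred)
    return PairScore(
        image_id=image_id,
        image_size=tuple(np.asarray(truth).shape),
        counts=counts,
        jaccard_p=jaccard(counts),
        dice=dice(counts),
    )


def evaluate_batch(pairs) -> pd.DataFrame:
    """Score a batch of (prediction, truth, id) triples.

    Returns a DataFrame with one row per pair (columns: id, image_size,
    intersection_px, union_px, P, DSC, status) plus a final "mean" row
    carrying the mean P and DSC over the successfully scored pairs.  A
    shape mismatch marks that row failed and the batch continues.
    """
    rows = []
    for pred, truth, image_id in pairs:
        try:
            s = score_pair(pred, truth, image_id=str(image_id))
        except ValueError as exc:
            rows.append(
                {
                    "id": str(image_id),
                    "image_size": "",
                    "intersection_px": np.nan,
                    "union_px": np.nan,
                    "P": np.nan,
                    "DSC": np.nan,
                    "status": f"failed: {exc}",
                }
            )
            continue
        rows.append(
            {
                "id": s.image_id,
                "image_size": f"{s.image_size[0]}x{s.image_size[1]}",
                "intersection_px": s.counts.intersection_px,
                "union_px": s.counts.union_px,
                "P": s.jaccard_p,
                "DSC": s.dice,
                "status": "ok",
            }
        )
    if not rows:
        raise ValueError("evaluate_batch needs at least one pair")
    df = pd.DataFrame(rows)
    ok = df[df["status"] == "ok"]
    mean_row = {
        "id": "mean",
        "image_size": "",
        "intersection_px": np.nan,
        "union_px": np.nan,
        "P": ok["P"].mean() if len(ok) else np.nan,
        "DSC": ok["DSC"].mean() if len(ok) else np.nan,
        "status": f"{len(ok)}/{len(df)} ok",
    }
    return pd.concat([df, pd.DataFrame([mean_row])], ignore_index=True)
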