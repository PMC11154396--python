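"""Segmentation, detection and score-agreement metrics.

* Dice overlap per merged tissue class, with the reported "average" being
  the mean of the tumor and stroma coefficients.
* Greedy one-to-one point matching: predictions claim, in descending
  confidence order, the nearest unmatched ground-truth point within the
  match radius (inclusive, default 8 px).
* FROC: sensitivity against average false positives per image, swept over
  the unique detection confidences; the FROC score is the mean of the best
  sensitivities attainable at fixed FP-per-image budgets
  (10, 20, 50, 100, 200, 300) under a step (no-extrapolation) rule.
* Pearson product-moment correlation between predicted and reference TIL
  scores, with undefined-score slides excluded pairwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .constants import FP_TARGETS, MATCH_RADIUS, MERGED_STROMA, MERGED_TUMOR
from .detection import DetectionSet

__all__ = [
    "MatchResult",
    "FROCCurve",
    "dice",
    "per_class_dice",
    "match_detections",
    "froc_curve",
    "froc_score",
    "pearson",
]


@dataclass(frozen=True)
class MatchResult:
    tp: int
    fp: int
    fn: int
    pairs: tuple[tuple[int, int, float], ...]  # (pred idx, gt idx, distance)


@dataclass(frozen=True)
class FROCCurve:
    """Operating points (threshold, avg FP/image, sensitivity), thresholds descending."""

    points: tuple[tuple[float, float, float], ...]

    def __len__(self) -> int:
        return len(self.points)


def dice(pred: np.ndarray, gt: np.ndarray) -> float:
    """Dice overlap 2|P∩G| / (|P|+|G|); two empty masks agree perfectly (1.0)."""
    pred = np.asarray(pred).astype(bool)
    gt = np.asarray(gt).astype(bool)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    denom = int(pred.sum()) + int(gt.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((pred & gt).sum()) / denom


def per_class_dice(pred: np.ndarray, gt: np.ndarray) -> dict[str, float]:
    """Dice of each merged class's binary indicator, plus the tumor/stroma average.

    Returns ``{"tumor": ..., "stroma": ..., "other": ..., "average": ...}``
    where ``average`` is the mean of the tumor and stroma coefficients only.
    """
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    out = {
        "tumor": dice(pred == MERGED_TUMOR, gt == MERGED_TUMOR),
        "stroma": dice(pred == MERGED_STROMA, gt == MERGED_STROMA),
        "other": dice(pred == 0, gt == 0),
    }
    out["average"] = (out["tumor"] + out["stroma"]) / 2.0
    return out


def match_detections(
    pred: DetectionSet,
    gt: list[tuple[float, float]] | np.ndarray,
    match_radius: float = MATCH_RADIUS,
) -> MatchResult:
    """Greedy one-to-one matching of detections to ground-truth points.

    Predictions are visited in confidence-descending order (the
    :class:`DetectionSet` sort); each claims the nearest still-unmatched
    ground-truth point within ``match_radius``, inclusive.  Unclaimed
    predictions are false positives; unclaimed ground-truth points are
    false negatives.
    """
    gt = np.asarray(gt, dtype=float).reshape(-1, 2)
    taken = np.zeros(len(gt), dtype=bool)
    pairs: list[tuple[int, int, float]] = []
    for pi, det in enumerate(pred):
        if len(gt) == 0:
            break
        dx = gt[:, 0] - det.x
        dy = gt[:, 1] - det.y
        dist = np.hypot(dx, dy)
        dist[taken] = np.inf
        gi = int(np.argmin(dist))
        if dist[gi] <= match_radius:
            taken[gi] = True
            pairs.append((pi, gi, float(dist[gi])))
    tp = len(pairs)
    return MatchResult(tp=tp, fp=len(pred) - tp, fn=len(gt) - tp, pairs=tuple(pairs))


def froc_curve(
    per_image: list[tuple[DetectionSet, list | np.ndarray]],
    match_radius: float = MATCH_RADIUS,
) -> FROCCurve:
    """FROC operating points over the unique confidence thresholds.

    For each threshold (unique confidences, descending) the detections at or
    above it are matched per image and the point
    (threshold, total FP / n_images, total TP / total GT) is recorded.  A
    detector with no detections yields an empty curve (sensitivity 0
    everywhere by convention).
    """
    if not per_image:
        raise ValueError("need at least one image")
    n_gt = sum(len(np.asarray(g, dtype=float).reshape(-1, 2)) for _, g in per_image)
    if n_gt == 0:
        raise ValueError("no ground-truth points: sensitivity undefined")
    n_images = len(per_image)
    confs = np.concatenate([d.confidences() for d, _ in per_image]) if per_image else np.array([])
    thresholds = np.unique(confs)[::-1]
    points = []
    for t in thresholds:
        tp_tot = fp_tot = 0
        for dets, gt in per_image:
            res = match_detections(dets.at_threshold(float(t)), gt, match_radius)
            tp_tot += res.tp
            fp_tot += res.fp
        points.append((float(t), fp_tot / n_images, tp_tot / n_gt))
    return FROCCurve(tuple(points))


def froc_score(
    curve: FROCCurve, fp_targets: tuple[float, ...] = FP_TARGETS
) -> float:
    """Mean sensitivity at the fixed FP-per-image budgets.

    For each target the best sensitivity over operating points with
    avg FP/image <= target is taken (0 if no point qualifies — the step
    rule never extrapolates); the score is the mean over the targets.
    """
    out = []
    for target in fp_targets:
        best = 0.0
        for _, fp_rate, sens in curve.points:
            if fp_rate <= target and sens > best:
                best = sens
        out.append(best)
    return float(np.mean(out))


def pearson(
    pred_scores, ref_scores
) -> float:
    """Pearson correlation between predicted and reference TIL scores.

    Pairs where either score is undefined (None/NaN) are excluded; at least
    three pairs with non-zero variance on both sides are required.
    """
    pred = np.asarray([math.nan if v is None else v for v in pred_scores], dtype=float)
    ref = np.asarray([math.nan if v is None else v for v in ref_scores], dtype=float)
    if pred.shape != ref.shape:
        raise ValueError("score vectors must have equal length")
    ok = ~(np.isnan(pred) | np.isnan(ref))
    pred, ref = pred[ok], ref[ok]
    if len(pred) < 3:
        raise ValueError(f"need >= 3 defined score pairs, have {len(pred)}")
    if np.ptp(pred) == 0 or np.ptp(ref) == 0:
        raise ValueError("zero variance in scores: correlation undefined")
    r, _ = stats.pearsonr(pred, ref)
    return float(r)
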