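"""Lymphocyte candidate extraction and distance-based non-maximum suppression.

A detection probability map is reduced to a confidence-ranked point set in
two steps: every pixel whose probability strictly exceeds the retention
threshold (default 0.1) becomes a candidate, and a greedy scan in descending
confidence order keeps a candidate only if it lies at least ``nms_distance``
(default 12 px, the lymphocyte box side) from every already-kept detection —
one detection per lymphocyte-sized neighborhood.

Suppression is strict (``< nms_distance`` suppresses, ``>=`` keeps): two
12-px boxes whose centers are exactly 12 apart do not overlap.  Ties in
confidence are broken by (y, x) lexicographic order, so the output is
deterministic across platforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import CANDIDATE_THRESHOLD, NMS_DISTANCE

__all__ = ["Candidate", "DetectionSet", "extract_candidates", "distance_nms", "detect"]


@dataclass(frozen=True)
class Candidate:
    x: int
    y: int
    confidence: float


@dataclass(frozen=True)
class DetectionSet:
    """Confidence-ranked lymphocyte points.

    ``detections`` is sorted by confidence descending (ties by (y, x));
    when produced by :func:`distance_nms`, any two detections are at least
    the NMS distance apart.
    """

    detections: tuple[Candidate, ...]
    frame: str = "slide"

    def __len__(self) -> int:
        return len(self.detections)

    def __iter__(self):
        return iter(self.detections)

    def xy(self) -> np.ndarray:
        """(n, 2) float array of (x, y) coordinates."""
        if not self.detections:
            return np.empty((0, 2), dtype=float)
        return np.array([(d.x, d.y) for d in self.detections], dtype=float)

    def confidences(self) -> np.ndarray:
        return np.array([d.confidence for d in self.detections], dtype=float)

    def at_threshold(self, threshold: float) -> "DetectionSet":
        """Subset with confidence >= threshold (order preserved)."""
        kept = tuple(d for d in self.detections if d.confidence >= threshold)
        return DetectionSet(kept, frame=self.frame)


def extract_candidates(
    det_map: np.ndarray, tau: float = CANDIDATE_THRESHOLD
) -> list[Candidate]:
    """Candidates = pixels with probability strictly greater than ``tau``.

    Returned sorted by confidence descending, ties broken by (y, x)
    lexicographic order.  A pixel exactly at ``tau`` is excluded.
    """
    det_map = np.asarray(det_map, dtype=float)
    if det_map.ndim != 2:
        raise ValueError(f"detection map must be 2-D, got shape {det_map.shape}")
    if det_map.size and (det_map.min() < 0.0 or det_map.max() > 1.0):
        raise ValueError("detection map values must lie in [0, 1]")
    ys, xs = np.nonzero(det_map > tau)
    confs = det_map[ys, xs]
    # descending confidence, then ascending (y, x)
    order = np.lexsort((xs, ys, -confs))
    return [
        Candidate(int(xs[i]), int(ys[i]), float(confs[i])) for i in order
    ]


def distance_nms(
    candidates: list[Candidate], nms_distance: float = NMS_DISTANCE
) -> DetectionSet:
    """Greedy hard-core selection over confidence-sorted candidates.

    Scans candidates in the order produced by :func:`extract_candidates` and
    keeps one iff its Euclidean distance to every already-kept detection is
    >= ``nms_distance``.  Idempotent: re-running on its own output changes
    nothing.

    Uses a spatial hash with cell size ``nms_distance`` so only the 3x3
    neighborhood of cells needs checking per candidate.
    """
    if nms_distance < 0:
        raise ValueError("nms_distance must be >= 0")
    if nms_distance == 0 or len(candidates) <= 1:
        return DetectionSet(tuple(candidates))
    cell = nms_distance
    d2 = nms_distance * nms_distance
    buckets: dict[tuple[int, int], list[tuple[float, float]]] = {}
    kept: list[Candidate] = []
    for c in candidates:
        ci, cj = math.floor(c.x / cell), math.floor(c.y / cell)
        ok = True
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for (kx, ky) in buckets.get((ci + di, cj + dj), ()):
                    if (c.x - kx) ** 2 + (c.y - ky) ** 2 < d2:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            kept.append(c)
            buckets.setdefault((ci, cj), []).append((float(c.x), float(c.y)))
    return DetectionSet(tuple(kept))


def detect(
    det_map: np.ndarray,
    tau: float = CANDIDATE_THRESHOLD,
    nms_distance: float = NMS_DISTANCE,
) -> DetectionSet:
    """Threshold a probability map and suppress near-duplicates.

    Composition of :func:`extract_candidates` and :func:`distance_nms`.
    """
    return distance_nms(extract_candidates(det_map, tau), nms_distance)
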