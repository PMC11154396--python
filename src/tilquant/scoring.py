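"""Stroma-restricted TIL score.

The score expresses the area that detected lymphocytes would occupy as a
percentage of the stromal area of a slide:

    TIL score = 100 * sum(n_tils * A_lym) / sum(stroma_pixels)

where ``n_tils`` counts detections whose center pixel falls inside the
stroma compartment, ``A_lym`` is the pixel footprint of one lymphocyte
(16 x 16 = 256 px^2 — an 8 um equivalent diameter at 0.5 um/px), and the
sums run over a slide's retained patches before the division.  The raw
ratio can exceed 100 under dense detections; the reported score is clipped
to [0, 100] while the raw value is preserved in the record.  A slide with
no stroma pixels has no meaningful score and is marked undefined rather
than zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .constants import LYMPHOCYTE_AREA_PX, MERGED_STROMA
from .detection import DetectionSet
from .preprocessing import PatchGrid

logger = logging.getLogger(__name__)

__all__ = [
    "TILScoreRecord",
    "lymphocyte_area_px",
    "stroma_mask",
    "count_in_stroma",
    "compute_score",
    "slide_score",
    "score_slide",
]


@dataclass(frozen=True)
class TILScoreRecord:
    """Per-slide numerator/denominator bookkeeping and the resulting score."""

    slide_id: str
    n_tils_in_stroma: int
    stroma_pixels: int
    lymphocyte_area: int = LYMPHOCYTE_AREA_PX
    raw_score: float | None = None  # unclipped; None when undefined
    score: float | None = None  # clipped to [0, 100]; None when undefined

    @property
    def defined(self) -> bool:
        return self.score is not None


def lymphocyte_area_px(
    diameter_um: float = 8.0, resolution_um_per_px: float = 0.5
) -> int:
    """Pixel footprint of one lymphocyte: (diameter / resolution)^2.

    Default 8 um at 0.5 um/px gives the 16 x 16 = 256 px^2 convention.
    """
    side = diameter_um / resolution_um_per_px
    return int(round(side) ** 2)


def stroma_mask(seg) -> np.ndarray:
    """Binary stroma mask from a probability map or a merged label raster.

    A (H, W, 3) float input is read as per-pixel class probabilities in
    channel order (tumor, stroma, other); a pixel is stroma iff the argmax
    channel is stroma, with ties resolved toward the lowest channel index
    (tumor before stroma before other).  A 2-D integer input is read as
    merged labels and compared against the stroma label.
    """
    seg = np.asarray(seg)
    if seg.ndim == 3:
        if seg.shape[2] != 3:
            raise ValueError(f"expected 3 channels (tumor, stroma, other), got {seg.shape[2]}")
        # np.argmax returns the first maximal index: ties go to lower channel.
        return (np.argmax(seg, axis=2) == 1).astype(np.uint8)
    if seg.ndim == 2 and np.issubdtype(seg.dtype, np.integer):
        return (seg == MERGED_STROMA).astype(np.uint8)
    raise ValueError("seg must be an (H, W, 3) probability map or a 2-D merged label raster")


def count_in_stroma(dets: DetectionSet, stroma: np.ndarray) -> int:
    """Number of detections whose rounded (x, y) pixel lies on stroma.

    Membership uses the center pixel only, not the lymphocyte footprint:
    the score numerator counts lymphocytes, not pixels.
    """
    stroma = np.asarray(stroma)
    h, w = stroma.shape
    n = 0
    for d in dets:
        xi, yi = int(round(d.x)), int(round(d.y))
        if not (0 <= xi < w and 0 <= yi < h):
            raise ValueError(f"detection ({d.x}, {d.y}) outside raster bounds {(h, w)}")
        if stroma[yi, xi]:
            n += 1
    return n


def compute_score(
    n_tils: int,
    stroma_pixels: int,
    lymphocyte_area: int = LYMPHOCYTE_AREA_PX,
    slide_id: str = "",
) -> TILScoreRecord:
    """Evaluate the score ratio for one slide.

    Returns an undefined record (``score is None``) when ``stroma_pixels``
    is zero; otherwise ``100 * n_tils * lymphocyte_area / stroma_pixels``
    clipped to [0, 100], with the raw ratio preserved.
    """
    if n_tils < 0 or stroma_pixels < 0:
        raise ValueError("counts must be non-negative")
    if stroma_pixels == 0:
        logger.warning("slide %s has no stroma pixels; TIL score undefined", slide_id or "<?>")
        return TILScoreRecord(slide_id, n_tils, 0, lymphocyte_area, None, None)
    raw = 100.0 * n_tils * lymphocyte_area / stroma_pixels
    score = min(100.0, max(0.0, raw))
    if raw > 100.0:
        logger.warning("slide %s raw TIL score %.1f clipped to 100", slide_id or "<?>", raw)
    return TILScoreRecord(slide_id, n_tils, stroma_pixels, lymphocyte_area, raw, score)


def slide_score(
    patch_records: list[tuple[int, int]],
    lymphocyte_area: int = LYMPHOCYTE_AREA_PX,
    slide_id: str = "",
) -> TILScoreRecord:
    """Aggregate per-patch (n_tils, stroma_pixels) into one slide score.

    Numerator and denominator are summed across patches before the single
    division, so any tiling of a slide yields the same score as the untiled
    slide (given no patches are dropped).
    """
    if not patch_records:
        logger.warning("slide %s has no retained patches; TIL score undefined", slide_id or "<?>")
        return TILScoreRecord(slide_id, 0, 0, lymphocyte_area, None, None)
    n = int(sum(r[0] for r in patch_records))
    a = int(sum(r[1] for r in patch_records))
    return compute_score(n, a, lymphocyte_area, slide_id)


def score_slide(
    dets: DetectionSet,
    stroma: np.ndarray,
    grid: PatchGrid | None = None,
    lymphocyte_area: int = LYMPHOCYTE_AREA_PX,
    slide_id: str = "",
) -> TILScoreRecord:
    """Score one slide from its detections, stroma mask and retained windows.

    With ``grid`` given (typically the background-filtered tiling), each
    retained window contributes a (count, stroma-area) pair and the pairs are
    aggregated by :func:`slide_score`; detections outside every retained
    window do not count.  Without a grid the whole raster is one window.
    """
    stroma = np.asarray(stroma)
    if grid is None:
        n = count_in_stroma(dets, stroma)
        return compute_score(n, int(stroma.sum()), lymphocyte_area, slide_id)
    h, w = stroma.shape
    records: list[tuple[int, int]] = []
    pts = [(int(round(d.x)), int(round(d.y))) for d in dets]
    for win in grid.windows:
        y1, x1 = min(win.y1, h), min(win.x1, w)
        area = int(stroma[win.y0 : y1, win.x0 : x1].sum())
        cnt = sum(
            1
            for (xi, yi) in pts
            if win.x0 <= xi < x1 and win.y0 <= yi < y1 and stroma[yi, xi]
        )
        records.append((cnt, area))
    return slide_score(records, lymphocyte_area, slide_id)
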