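"""Synthetic slide generator with full ground truth.

Emulates the structure of a TIL-assessment cohort at desk scale: each
"slide" is a 512–4096 px raster carrying

* a fine tissue label map over the eight-class vocabulary, generated as
  smoothed Gaussian random fields thresholded at class-fraction quantiles
  (contiguous blobs, exact per-class pixel fractions);
* lymphocyte points from a per-class homogeneous Poisson process with
  hard-core thinning (earlier-drawn point wins), rates highest in the
  stromal classes — TILs are lymphocytes within stroma;
* corrupted segmentation / detection probability maps standing in for the
  outputs of learned models, with a single difficulty knob ``noise_sigma``;
* COCO-style 12 x 12 box annotations centered on the points;
* the slide's true TIL score, computed by the scoring module on the
  noise-free truth with the same tiling and background-exclusion rules the
  pipeline applies.

Determinism: every output is a pure function of (params, seed).  Each
generation stage draws from ``numpy.random.default_rng([stage_key, seed])``
so stages are independent and individually reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .constants import (
    FINE_CLASSES,
    FINE_NAME_TO_ID,
    MERGED_TUMOR,
    MERGED_STROMA,
    SEG_CHANNEL_TO_MERGED,
    MAX_BACKGROUND_FRACTION,
    TILE_SIDE,
    BOX_SIDE,
)
from .preprocessing import TissueLabelMap, tile_image, background_fraction, filter_patches
from . import io as tio
from .detection import Candidate, DetectionSet
from .scoring import score_slide

__all__ = [
    "SynthParams",
    "SlideTruth",
    "generate_tissue_map",
    "sample_lymphocyte_points",
    "render_probability_maps",
    "emit_annotations",
    "simulate_slide",
    "generate_cohort",
]

# RNG stage keys (first entry of the seed sequence) — one stream per stage.
_K_TISSUE, _K_POINTS, _K_MAPS, _K_COHORT = 11, 23, 37, 53

#: Default area fractions: a tumor-rich biopsy region with one quarter
#: unstained background.
DEFAULT_CLASS_FRACTIONS: dict[str, float] = {
    "invasive_tumor": 0.22,
    "tumor_associated_stroma": 0.25,
    "in_situ_tumor": 0.03,
    "healthy_glands": 0.05,
    "necrosis": 0.04,
    "inflamed_stroma": 0.08,
    "rest": 0.08,
    "background": 0.25,
}

#: Expected lymphocytes per pixel by fine class.  Inflamed stroma carries
#: the densest infiltrate, tumor-associated stroma a moderate one, epithelial
#: compartments scattered cells, background none.  At the default fractions
#: on a 1024 px slide this yields true TIL scores around 10%.
DEFAULT_LYMPHO_RATE: dict[str, float] = {
    "invasive_tumor": 5e-5,
    "tumor_associated_stroma": 3e-4,
    "in_situ_tumor": 2e-5,
    "healthy_glands": 2e-5,
    "necrosis": 1e-5,
    "inflamed_stroma": 8e-4,
    "rest": 2e-5,
    "background": 0.0,
}


@dataclass(frozen=True)
class SynthParams:
    """Generator parameters for one synthetic slide.

    ``noise_sigma`` scales every corruption applied to the probability
    maps; 0 reproduces the ground truth exactly.  ``blur_radius`` is the
    Gaussian radius (px) of the detection bumps; ``seg_blur_radius``
    optionally smooths the segmentation channels.
    """

    width: int = 1024
    height: int = 1024
    class_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_FRACTIONS)
    )
    blob_scale: float = 64.0
    lympho_rate: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_LYMPHO_RATE))
    min_separation: float = 12.0
    noise_sigma: float = 0.0
    blur_radius: float = 3.0
    seg_blur_radius: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError(f"dimensions must be positive, got {self.width}x{self.height}")
        fr = np.array(list(self.class_fractions.values()), dtype=float)
        if (fr < 0).any():
            raise ValueError("class fractions must be non-negative")
        if abs(fr.sum() - 1.0) > 1e-9:
            raise ValueError(f"class fractions must sum to 1, got {fr.sum()!r}")
        unknown = set(self.class_fractions) - set(FINE_NAME_TO_ID)
        if unknown:
            raise ValueError(f"unknown fine classes: {sorted(unknown)}")
        if any(v < 0 for v in self.lympho_rate.values()):
            raise ValueError("lymphocyte rates must be non-negative")
        if self.min_separation < 0 or self.noise_sigma < 0 or self.blur_radius < 0:
            raise ValueError("min_separation, noise_sigma and blur_radius must be >= 0")


@dataclass(frozen=True)
class SlideTruth:
    """Ground truth for one synthetic slide."""

    slide_id: str
    tissue: TissueLabelMap
    points: tuple[tuple[int, int], ...]  # (x, y) pixel coordinates
    true_til_score: float | None  # None when undefined (no retained stroma)


def generate_tissue_map(params: SynthParams) -> TissueLabelMap:
    """Contiguous-blob fine tissue map with exact class fractions.

    A standard-normal field is smoothed at ``blob_scale / 4`` and its rank
    order partitioned at the cumulative class fractions; each quantile band
    becomes one class (insertion order of ``class_fractions``).  Level sets
    of a smooth field are spatially contiguous, and rank partitioning makes
    the empirical fractions exact up to integer rounding.
    """
    rng = np.random.default_rng([_K_TISSUE, params.seed])
    h, w = params.height, params.width
    names = list(params.class_fractions)
    fracs = np.array([params.class_fractions[n] for n in names], dtype=float)
    if len(names) == 1:
        px = np.full((h, w), FINE_NAME_TO_ID[names[0]], dtype=np.uint8)
        return TissueLabelMap(px)
    field_ = rng.standard_normal((h, w))
    sigma = max(params.blob_scale / 4.0, 1e-6)
    field_ = ndimage.gaussian_filter(field_, sigma=sigma)
    order = np.argsort(field_, axis=None, kind="stable")
    counts = np.floor(fracs * h * w).astype(int)
    counts[-1] += h * w - counts.sum()  # remainder to the last class
    px = np.empty(h * w, dtype=np.uint8)
    start = 0
    for name, cnt in zip(names, counts):
        px[order[start : start + cnt]] = FINE_NAME_TO_ID[name]
        start += cnt
    return TissueLabelMap(px.reshape(h, w))


def sample_lymphocyte_points(
    tissue: TissueLabelMap, params: SynthParams
) -> list[tuple[int, int]]:
    """Per-class Poisson point process with hard-core thinning.

    For each fine class present in the raster, a Poisson count with mean
    ``rate * class_area`` is drawn and that many pixels sampled uniformly
    within the class; the pooled draw is then thinned so that every kept
    point is at least ``min_separation`` px from all earlier-kept points.
    """
    if tissue.shape != (params.height, params.width):
        raise ValueError("tissue raster and params dimensions differ")
    rng = np.random.default_rng([_K_POINTS, params.seed])
    h, w = tissue.shape
    raw: list[tuple[int, int]] = []
    present = np.unique(tissue.pixels)
    for cid in present.tolist():
        name = tissue.legend[cid]
        if name not in params.lympho_rate:
            raise ValueError(f"lympho_rate missing class {name!r} present in tissue")
        rate = params.lympho_rate[name]
        if rate == 0:
            continue
        flat = np.flatnonzero(tissue.pixels.ravel() == cid)
        n = rng.poisson(rate * flat.size)
        if n == 0:
            continue
        picks = rng.choice(flat, size=n, replace=True)
        raw.extend((int(p % w), int(p // w)) for p in picks)
    if params.min_separation <= 0:
        return raw
    kept = _hardcore_thin(raw, params.min_separation)
    return kept


def _hardcore_thin(
    points: list[tuple[int, int]], min_sep: float
) -> list[tuple[int, int]]:
    """Keep each point iff it is >= min_sep from every earlier-kept point."""
    cell = min_sep
    d2 = min_sep * min_sep
    buckets: dict[tuple[int, int], list[tuple[int, int]]] = {}
    kept: list[tuple[int, int]] = []
    for x, y in points:
        ci, cj = int(np.floor(x / cell)), int(np.floor(y / cell))
        ok = True
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for (kx, ky) in buckets.get((ci + di, cj + dj), ()):
                    if (x - kx) ** 2 + (y - ky) ** 2 < d2:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            kept.append((x, y))
            buckets.setdefault((ci, cj), []).append((x, y))
    return kept


def render_probability_maps(
    tissue: TissueLabelMap,
    points: list[tuple[int, int]],
    params: SynthParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Corrupted (seg, det) probability maps standing in for model outputs.

    Segmentation: the merged truth one-hot over channels (tumor, stroma,
    other) is perturbed with i.i.d. Gaussian noise of std ``noise_sigma``,
    optionally blurred (``seg_blur_radius``), clipped at zero and
    renormalized so every pixel is a probability vector.

    Detection: each lymphocyte contributes a Gaussian bump of radius
    ``blur_radius`` (an impulse when 0) peaking at its confidence; bumps
    combine by maximum.  ``noise_sigma`` corrupts the map through a
    detector-error model — peak-height jitter (confidence
    ``clip(1 - |N(0, sigma)|)``, occasionally dropping a cell below the
    candidate threshold), position jitter (std ``4 * sigma`` px), spurious
    peaks (Poisson rate ``sigma`` per true cell, confidences in
    [0, sigma]), and a low-amplitude i.i.d. pixel noise floor
    (std ``sigma / 20``, clipped to [0, 1]).
    """
    if tissue.shape != (params.height, params.width):
        raise ValueError("tissue raster and params dimensions differ")
    h, w = tissue.shape
    s = params.noise_sigma
    rng = np.random.default_rng([_K_MAPS, params.seed])

    merged = tissue.merged_view
    seg = np.zeros((h, w, 3), dtype=np.float32)
    for ch, label in enumerate(SEG_CHANNEL_TO_MERGED):
        seg[..., ch] = merged == label
    if s > 0:
        seg = seg + rng.normal(0.0, s, size=seg.shape).astype(np.float32)
    if params.seg_blur_radius > 0:
        for ch in range(3):
            seg[..., ch] = ndimage.gaussian_filter(seg[..., ch], params.seg_blur_radius)
    seg = np.clip(seg, 0.0, None)
    total = seg.sum(axis=2, keepdims=True)
    flat = total[..., 0] <= 1e-12
    seg[flat] = 1.0 / 3.0
    total[flat[..., None]] = 1.0
    seg = (seg / total).astype(np.float32)

    peaks: list[tuple[float, float, float]] = []  # (x, y, confidence)
    for x, y in points:
        if s > 0:
            conf = float(np.clip(1.0 - abs(rng.normal(0.0, s)), 0.0, 1.0))
            x = int(np.clip(round(x + rng.normal(0.0, 4.0 * s)), 0, w - 1))
            y = int(np.clip(round(y + rng.normal(0.0, 4.0 * s)), 0, h - 1))
        else:
            conf = 1.0
        peaks.append((x, y, conf))
    if s > 0:
        n_fp = rng.poisson(s * max(len(points), 1))
        fx = rng.integers(0, w, size=n_fp)
        fy = rng.integers(0, h, size=n_fp)
        fconf = rng.uniform(0.0, s, size=n_fp)
        peaks.extend(zip(fx.tolist(), fy.tolist(), np.clip(fconf, 0, 1).tolist()))

    det = np.zeros((h, w), dtype=np.float32)
    r = params.blur_radius
    if r > 0:
        half = int(np.ceil(3.0 * r))
        yy, xx = np.mgrid[-half : half + 1, -half : half + 1]
        kernel = np.exp(-(xx**2 + yy**2) / (2.0 * r * r)).astype(np.float32)
    for px, py, conf in peaks:
        if conf <= 0:
            continue
        if r == 0:
            det[int(py), int(px)] = max(det[int(py), int(px)], conf)
            continue
        x0, x1 = int(px) - half, int(px) + half + 1
        y0, y1 = int(py) - half, int(py) + half + 1
        kx0, ky0 = max(0, -x0), max(0, -y0)
        x0, y0 = max(0, x0), max(0, y0)
        x1, y1 = min(w, x1), min(h, y1)
        sub = kernel[ky0 : ky0 + (y1 - y0), kx0 : kx0 + (x1 - x0)] * conf
        np.maximum(det[y0:y1, x0:x1], sub, out=det[y0:y1, x0:x1])
    if s > 0:
        det = det + rng.normal(0.0, s / 20.0, size=det.shape).astype(np.float32)
    det = np.clip(det, 0.0, 1.0).astype(np.float32)
    return seg, det


def _round_half_up(v: float) -> int:
    return int(np.floor(v + 0.5))


def emit_annotations(
    points: list[tuple[int, int]],
    box_side: int = BOX_SIDE,
    slide_id: str = "slide",
    image_size: tuple[int, int] | None = None,
) -> "tio.CocoAnnotationSet":
    """COCO records with a ``box_side`` square centered on each point.

    bbox = [round(x - box_side/2), round(y - box_side/2), box_side, box_side].
    """
    if box_side < 1:
        raise ValueError("box_side must be >= 1")
    h, w = image_size if image_size is not None else (0, 0)
    images = [{"id": 1, "file_name": f"{slide_id}.png", "width": int(w), "height": int(h)}]
    annotations = [
        {
            "id": i + 1,
            "image_id": 1,
            "category_id": 1,
            "bbox": [
                _round_half_up(x - box_side / 2.0),
                _round_half_up(y - box_side / 2.0),
                box_side,
                box_side,
            ],
            "area": box_side * box_side,
        }
        for i, (x, y) in enumerate(points)
    ]
    categories = [{"id": 1, "name": "lymphocyte"}]
    return tio.CocoAnnotationSet(images=images, annotations=annotations, categories=categories)


def true_til_score(
    tissue: TissueLabelMap,
    points,
    tile_side: int = TILE_SIDE,
    max_bg: float = MAX_BACKGROUND_FRACTION,
    lymphocyte_area: int | None = None,
    slide_id: str = "",
):
    """Reference TIL score from the noise-free truth.

    Applies the same procedure as the prediction pipeline — tile, exclude
    patches whose background fraction exceeds ``max_bg``, count points on
    truth stroma within retained windows, divide summed numerator by summed
    stroma area — so that a perfect detector/segmenter recovers it exactly.
    """
    from .constants import LYMPHOCYTE_AREA_PX

    grid = tile_image(tissue.pixels, tile_side)
    fracs = [
        background_fraction(grid.extract(tissue.pixels, wdw), "label", legend=tissue.legend)
        for wdw in grid.windows
    ]
    kept = filter_patches(grid, fracs, max_bg)
    dets = DetectionSet(tuple(Candidate(x, y, 1.0) for x, y in points))
    stroma = (tissue.merged_view == MERGED_STROMA).astype(np.uint8)
    area = LYMPHOCYTE_AREA_PX if lymphocyte_area is None else lymphocyte_area
    return score_slide(dets, stroma, kept, area, slide_id)


def simulate_slide(
    params: SynthParams,
    slide_id: str = "slide_000",
    tile_side: int = TILE_SIDE,
    max_bg: float = MAX_BACKGROUND_FRACTION,
) -> tuple[SlideTruth, np.ndarray, np.ndarray]:
    """Generate one slide in memory: truth plus (seg, det) probability maps."""
    tissue = generate_tissue_map(params)
    points = sample_lymphocyte_points(tissue, params)
    seg, det = render_probability_maps(tissue, points, params)
    rec = true_til_score(tissue, points, tile_side, max_bg, slide_id=slide_id)
    truth = SlideTruth(slide_id, tissue, tuple(points), rec.score)
    return truth, seg, det


def cohort_slide_params(
    n_slides: int,
    params: SynthParams,
    rate_spread: tuple[float, float] = (0.3, 2.0),
) -> list[SynthParams]:
    """Per-slide parameter sets derived from one cohort seed.

    Each slide gets its own seed and a lymphocyte-rate multiplier drawn
    uniformly from ``rate_spread``, emulating inter-patient variability in
    infiltrate density (and guaranteeing score variance across the cohort).
    """
    if n_slides < 1:
        raise ValueError("n_slides must be >= 1")
    rng = np.random.default_rng([_K_COHORT, params.seed])
    child_seeds = rng.integers(0, 2**31 - 1, size=n_slides)
    factors = rng.uniform(rate_spread[0], rate_spread[1], size=n_slides)
    return [
        replace(
            params,
            seed=int(child_seeds[i]),
            lympho_rate={k: v * float(factors[i]) for k, v in params.lympho_rate.items()},
        )
        for i in range(n_slides)
    ]


def generate_cohort(
    n_slides: int,
    params: SynthParams,
    out_dir: str | Path,
    tile_side: int = TILE_SIDE,
    max_bg: float = MAX_BACKGROUND_FRACTION,
    rate_spread: tuple[float, float] = (0.3, 2.0),
) -> dict:
    """Write an n-slide cohort with ground truth and reference scores.

    Per-slide seeds and lymphocyte-rate multipliers (uniform in
    ``rate_spread``, emulating inter-patient variability in infiltrate
    density) derive from the cohort seed.  Writes per slide: tissue label
    PNG + legend JSON, segmentation / detection probability TIFFs, COCO
    annotation JSON; plus a cohort reference-score CSV and a manifest JSON.
    """
    if n_slides < 1:
        raise ValueError("n_slides must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    slides = []
    score_records = []
    for i, p in enumerate(cohort_slide_params(n_slides, params, rate_spread)):
        sid = f"slide_{i:03d}"
        truth, seg, det = simulate_slide(p, sid, tile_side, max_bg)
        sdir = out_dir / sid
        sdir.mkdir(exist_ok=True)
        tio.write_label_png(sdir / "tissue.png", truth.tissue.pixels, truth.tissue.legend)
        tio.write_prob_tiff(sdir / "seg_prob.tiff", seg)
        tio.write_prob_tiff(sdir / "det_prob.tiff", det)
        coco = emit_annotations(
            list(truth.points), slide_id=sid, image_size=truth.tissue.shape
        )
        tio.write_coco(sdir / "annotations.json", coco)
        slides.append(
            {
                "slide_id": sid,
                "dir": sid,
                "tissue": f"{sid}/tissue.png",
                "legend": f"{sid}/tissue.legend.json",
                "seg_prob": f"{sid}/seg_prob.tiff",
                "det_prob": f"{sid}/det_prob.tiff",
                "annotations": f"{sid}/annotations.json",
                "n_points": len(truth.points),
                "true_til_score": truth.true_til_score,
            }
        )
        score_records.append({"slide_id": sid, "til_score": truth.true_til_score})

    tio.write_reference_scores(out_dir / "reference-til-scores.csv", score_records)
    manifest = {
        "n_slides": n_slides,
        "seed": params.seed,
        "noise_sigma": params.noise_sigma,
        "tile_side": tile_side,
        "max_bg": max_bg,
        "slides": slides,
        "reference_scores": "reference-til-scores.csv",
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
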