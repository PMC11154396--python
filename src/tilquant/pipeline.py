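"""End-to-end orchestration: simulate -> preprocess -> detect -> score -> evaluate.

``run_pipeline`` drives a whole cohort from a :class:`PipelineConfig`:
generates (or loads) per-slide rasters and annotations, turns detection
probability maps into point sets, computes stroma-restricted TIL scores on
the background-filtered tiling, and evaluates Dice / FROC / Pearson against
the ground truth.  All intermediate artifacts and a metrics report are
written under ``output_dir``; every output records the config hash and seed
that produced it.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tio
from .config import PipelineConfig
from .detection import DetectionSet, detect
from .evaluation import froc_curve, froc_score, pearson, per_class_dice
from .preprocessing import (
    background_fraction,
    filter_patches,
    merge_classes,
    tile_image,
)
from .scoring import TILScoreRecord, score_slide, stroma_mask
from .synthetic import SynthParams, cohort_slide_params, generate_cohort, simulate_slide

logger = logging.getLogger(__name__)

__all__ = [
    "SlideResult",
    "run_pipeline",
    "run_cohort_in_memory",
    "evaluate_cohort",
    "prob_to_merged_labels",
]


def prob_to_merged_labels(seg: np.ndarray) -> np.ndarray:
    """Per-pixel argmax of a (H, W, 3) probability map as merged labels.

    Channel order (tumor, stroma, other) maps to labels (1, 2, 0); ties go
    to the lower channel index.
    """
    from .constants import SEG_CHANNEL_TO_MERGED

    seg = np.asarray(seg)
    if seg.ndim != 3 or seg.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) probability map, got shape {seg.shape}")
    lut = np.array(SEG_CHANNEL_TO_MERGED, dtype=np.uint8)
    return lut[np.argmax(seg, axis=2)]


@dataclass(frozen=True)
class SlideResult:
    slide_id: str
    detections: DetectionSet
    score_record: TILScoreRecord
    dice: dict[str, float]
    gt_points: np.ndarray  # (n, 2) box centers
    reference_score: float | None


def _process_slide(slide_dir: Path, entry: dict, cfg: PipelineConfig) -> SlideResult:
    pixels, legend = tio.read_label_png(slide_dir / "tissue.png")
    seg = tio.read_prob_tiff(slide_dir / "seg_prob.tiff", expect_channels=3)
    det_map = tio.read_prob_tiff(slide_dir / "det_prob.tiff", expect_channels=1)
    coco = tio.read_coco(slide_dir / "annotations.json")
    sid = entry["slide_id"]

    # preprocess: tile the slide and drop background-heavy windows
    grid = tile_image(pixels, cfg.tile_side)
    fracs = [
        background_fraction(grid.extract(pixels, w), "label", legend=legend)
        for w in grid.windows
    ]
    kept = filter_patches(grid, fracs, cfg.max_bg)
    logger.info(
        "slide %s: %d/%d windows retained after background filter",
        sid,
        len(kept.windows),
        len(grid.windows),
    )

    # detect: threshold + distance NMS on the probability map
    dets = detect(det_map, cfg.tau, cfg.nms_distance)

    # score: stroma-restricted TIL score on the retained windows
    stroma = stroma_mask(seg)
    record = score_slide(dets, stroma, kept, cfg.lymphocyte_area, sid)

    # segmentation quality on the merged view
    dice_scores = per_class_dice(prob_to_merged_labels(seg), merge_classes(pixels))

    return SlideResult(
        slide_id=sid,
        detections=dets,
        score_record=record,
        dice=dice_scores,
        gt_points=coco.centers(),
        reference_score=entry.get("true_til_score"),
    )


def evaluate_cohort(results: list[SlideResult], cfg: PipelineConfig) -> dict:
    """Cohort metrics: mean per-class Dice, FROC score, Pearson r."""
    dice_tumor = float(np.mean([r.dice["tumor"] for r in results]))
    dice_stroma = float(np.mean([r.dice["stroma"] for r in results]))
    curve = froc_curve(
        [(r.detections, r.gt_points) for r in results], cfg.match_radius
    )
    froc = froc_score(curve, cfg.fp_targets)
    pred = [r.score_record.score for r in results]
    ref = [r.reference_score for r in results]
    n_excluded = sum(1 for p, q in zip(pred, ref) if p is None or q is None)
    r_val = pearson(pred, ref)
    return {
        "dice_tumor": dice_tumor,
        "dice_stroma": dice_stroma,
        "dice_average": (dice_tumor + dice_stroma) / 2.0,
        "froc_score": froc,
        "pearson_r": r_val,
        "n_slides": len(results),
        "n_excluded_undefined": n_excluded,
        "froc_curve": [
            {"threshold": t, "avg_fp_per_image": f, "sensitivity": s}
            for t, f, s in curve.points
        ],
    }


def run_cohort_in_memory(cfg: PipelineConfig) -> tuple[list[SlideResult], dict]:
    """Simulate, process and evaluate a synthetic cohort without touching disk.

    Same computation as :func:`run_pipeline` with ``input_dir`` unset, minus
    serialization; used for parameter sweeps and property tests.
    """
    cfg.validate()
    base = SynthParams(
        width=cfg.slide_width,
        height=cfg.slide_height,
        noise_sigma=cfg.noise_sigma,
        seed=cfg.seed,
    )
    results = []
    for i, p in enumerate(cohort_slide_params(cfg.n_slides, base)):
        sid = f"slide_{i:03d}"
        truth, seg, det_map = simulate_slide(p, sid, cfg.tile_side, cfg.max_bg)
        pixels = truth.tissue.pixels
        grid = tile_image(pixels, cfg.tile_side)
        fracs = [
            background_fraction(grid.extract(pixels, w), "label", legend=truth.tissue.legend)
            for w in grid.windows
        ]
        kept = filter_patches(grid, fracs, cfg.max_bg)
        dets = detect(det_map, cfg.tau, cfg.nms_distance)
        record = score_slide(dets, stroma_mask(seg), kept, cfg.lymphocyte_area, sid)
        dice_scores = per_class_dice(prob_to_merged_labels(seg), merge_classes(pixels))
        results.append(
            SlideResult(
                slide_id=sid,
                detections=dets,
                score_record=record,
                dice=dice_scores,
                gt_points=np.asarray(truth.points, dtype=float).reshape(-1, 2),
                reference_score=truth.true_til_score,
            )
        )
    return results, evaluate_cohort(results, cfg)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full pipeline per the configuration; returns the run summary.

    When ``input_dir`` is unset, a synthetic cohort is generated under
    ``output_dir/cohort`` first.  Stage errors abort with the stage name and
    offending file in the exception context.
    """
    cfg.validate()
    out_dir = Path(cfg.output_dir or "tilquant_run")
    out_dir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    if cfg.input_dir is None:
        params = SynthParams(
            width=cfg.slide_width,
            height=cfg.slide_height,
            noise_sigma=cfg.noise_sigma,
            seed=cfg.seed,
        )
        manifest = generate_cohort(
            cfg.n_slides, params, out_dir / "cohort", cfg.tile_side, cfg.max_bg
        )
        cohort_dir = out_dir / "cohort"
    else:
        cohort_dir = Path(cfg.input_dir)
        with open(cohort_dir / "manifest.json") as fh:
            manifest = json.load(fh)
    timings["simulate"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    results = []
    for entry in manifest["slides"]:
        try:
            results.append(_process_slide(cohort_dir / entry["dir"], entry, cfg))
        except Exception as exc:
            raise RuntimeError(
                f"stage process-slide failed on {cohort_dir / entry['dir']}: {exc}"
            ) from exc
    timings["process"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    metrics = evaluate_cohort(results, cfg)
    timings["evaluate"] = time.perf_counter() - t0

    stamp = {"config_hash": cfg.config_hash(), "seed": cfg.seed}
    det_frames = []
    for r in results:
        det_frames.append(
            pd.DataFrame(
                {
                    "slide_id": r.slide_id,
                    "x": [d.x for d in r.detections],
                    "y": [d.y for d in r.detections],
                    "confidence": [d.confidence for d in r.detections],
                }
            )
        )
    pd.concat(det_frames, ignore_index=True).to_csv(out_dir / "detections.csv", index=False)
    tio.write_score_records(out_dir / "til-scores.csv", [r.score_record for r in results])
    pd.DataFrame(metrics["froc_curve"]).to_csv(out_dir / "froc-curve.csv", index=False)

    report = {**stamp, "config": cfg.to_dict(), "metrics": metrics, "timings": timings}
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    logger.info(
        "run complete: dice_avg=%.3f froc=%.3f pearson=%.3f (%d slides)",
        metrics["dice_average"],
        metrics["froc_score"],
        metrics["pearson_r"],
        metrics["n_slides"],
    )
    return report
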