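"""Readers and writers for the pipeline's on-disk formats.

* Tissue label maps: single-band 8-bit PNG with a JSON legend sidecar
  (``<name>.legend.json``) mapping raster value to fine class name.
* Probability maps: 32-bit float TIFF — (H, W, 3) for segmentation
  (channel order tumor, stroma, other), (H, W) for detection.
* Annotations: COCO-style JSON with ``images``, ``annotations`` (bbox as
  [x, y, w, h]) and ``categories``.
* Detections and scores: CSV via pandas.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .detection import Candidate, DetectionSet

__all__ = [
    "CocoAnnotationSet",
    "read_label_png",
    "write_label_png",
    "read_prob_tiff",
    "write_prob_tiff",
    "read_coco",
    "write_coco",
    "read_detections_csv",
    "write_detections_csv",
    "read_reference_scores",
    "write_reference_scores",
    "write_score_records",
]


# ---------------------------------------------------------------- rasters


def write_label_png(path: str | Path, pixels: np.ndarray, legend: dict[int, str]) -> None:
    """Write an integer label raster as 8-bit PNG plus a legend sidecar."""
    path = Path(path)
    pixels = np.asarray(pixels)
    if not np.issubdtype(pixels.dtype, np.integer):
        raise ValueError("label raster must be integer")
    if pixels.min() < 0 or pixels.max() > 255:
        raise ValueError("label values must fit in 8 bits")
    Image.fromarray(pixels.astype(np.uint8), mode="L").save(path)
    sidecar = path.with_suffix(".legend.json")
    with open(sidecar, "w") as fh:
        json.dump({str(k): v for k, v in legend.items()}, fh, indent=2)


def read_label_png(path: str | Path) -> tuple[np.ndarray, dict[int, str]]:
    """Read a label PNG and its legend sidecar."""
    path = Path(path)
    try:
        pixels = np.asarray(Image.open(path).convert("L"), dtype=np.uint8)
    except OSError as exc:
        raise IOError(f"cannot read label raster {path}: {exc}") from exc
    sidecar = path.with_suffix(".legend.json")
    if not sidecar.exists():
        raise IOError(f"missing legend sidecar {sidecar}")
    with open(sidecar) as fh:
        legend = {int(k): v for k, v in json.load(fh).items()}
    return pixels, legend


def write_prob_tiff(path: str | Path, arr: np.ndarray) -> None:
    """Write a float probability map as 32-bit TIFF ((H, W) or (H, W, C))."""
    arr = np.asarray(arr, dtype=np.float32)
    if arr.ndim not in (2, 3):
        raise ValueError(f"probability map must be 2-D or 3-D, got shape {arr.shape}")
    tifffile.imwrite(str(path), arr, photometric="minisblack")


def read_prob_tiff(path: str | Path, expect_channels: int | None = None) -> np.ndarray:
    """Read a float probability TIFF, optionally enforcing a channel count.

    ``expect_channels=1`` requires a single-band (2-D) map; ``expect_channels=n``
    requires shape (H, W, n).
    """
    path = Path(path)
    try:
        arr = tifffile.imread(str(path)).astype(np.float32)
    except (OSError, ValueError) as exc:
        raise IOError(f"cannot read probability map {path}: {exc}") from exc
    if expect_channels is not None:
        have = 1 if arr.ndim == 2 else arr.shape[2]
        if (expect_channels == 1) != (arr.ndim == 2) or (arr.ndim == 3 and have != expect_channels):
            raise IOError(
                f"{path}: expected {expect_channels} channel(s), found {have} (shape {arr.shape})"
            )
    return arr


# ------------------------------------------------------------ annotations


@dataclass(frozen=True)
class CocoAnnotationSet:
    """In-memory COCO-style annotation file (images/annotations/categories)."""

    images: list[dict] = field(default_factory=list)
    annotations: list[dict] = field(default_factory=list)
    categories: list[dict] = field(
        default_factory=lambda: [{"id": 1, "name": "lymphocyte"}]
    )

    def __len__(self) -> int:
        return len(self.annotations)

    def centers(self) -> np.ndarray:
        """(n, 2) array of box centers (x, y) — the underlying points."""
        if not self.annotations:
            return np.empty((0, 2), dtype=float)
        out = []
        for rec in self.annotations:
            x, y, w, h = rec["bbox"]
            out.append((x + w / 2.0, y + h / 2.0))
        return np.asarray(out, dtype=float)


def write_coco(path: str | Path, annotations: CocoAnnotationSet) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "images": annotations.images,
                "annotations": annotations.annotations,
                "categories": annotations.categories,
            },
            fh,
        )


def read_coco(path: str | Path) -> CocoAnnotationSet:
    """Read and validate a COCO-style JSON annotation file.

    Requires the ``annotations`` key; every record must carry a 4-element
    ``bbox`` and reference a declared category.
    """
    path = Path(path)
    try:
        with open(path) as fh:
            data = json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise IOError(f"cannot read annotations {path}: {exc}") from exc
    if "annotations" not in data:
        raise ValueError(f"{path}: missing 'annotations' key")
    categories = data.get("categories", [])
    known = {c["id"] for c in categories}
    for rec in data["annotations"]:
        rid = rec.get("id", "<?>")
        bbox = rec.get("bbox")
        if bbox is None or len(bbox) != 4:
            raise ValueError(f"{path}: annotation {rid} has no valid bbox")
        if known and rec.get("category_id") not in known:
            raise ValueError(
                f"{path}: annotation {rid} references unknown category {rec.get('category_id')}"
            )
    return CocoAnnotationSet(
        images=data.get("images", []),
        annotations=data["annotations"],
        categories=categories,
    )


# ------------------------------------------------------------------ CSVs


def write_detections_csv(path: str | Path, dets: DetectionSet, slide_id: str) -> None:
    pd.DataFrame(
        {
            "slide_id": slide_id,
            "x": [d.x for d in dets],
            "y": [d.y for d in dets],
            "confidence": [d.confidence for d in dets],
        }
    ).to_csv(path, index=False)


def read_detections_csv(path: str | Path) -> dict[str, DetectionSet]:
    df = pd.read_csv(path)
    out: dict[str, DetectionSet] = {}
    for sid, grp in df.groupby("slide_id", sort=False):
        dets = tuple(
            Candidate(int(r.x), int(r.y), float(r.confidence)) for r in grp.itertuples()
        )
        out[str(sid)] = DetectionSet(dets)
    return out


def write_reference_scores(path: str | Path, records: list[dict]) -> None:
    """Reference-score CSV: slide_id, til_score (blank when undefined)."""
    pd.DataFrame(records, columns=["slide_id", "til_score"]).to_csv(path, index=False)


def read_reference_scores(path: str | Path) -> dict[str, float | None]:
    df = pd.read_csv(path)
    out: dict[str, float | None] = {}
    for r in df.itertuples():
        v = float(r.til_score) if pd.notna(r.til_score) else None
        out[str(r.slide_id)] = v
    return out


def write_score_records(path: str | Path, records) -> None:
    """Per-slide TIL score CSV with numerator/denominator provenance."""
    pd.DataFrame(
        [
            {
                "slide_id": r.slide_id,
                "n_tils_in_stroma": r.n_tils_in_stroma,
                "stroma_pixels": r.stroma_pixels,
                "raw_score": r.raw_score,
                "score": r.score,
                "defined": r.defined,
            }
            for r in records
        ]
    ).to_csv(path, index=False)
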