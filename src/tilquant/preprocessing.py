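"""Slide preparation: tiling with zero-padding, background filtering,
fine-to-merged class mapping, and box-annotation rasterization.

Conventions used throughout the package: coordinates are 0-based with
``x`` = column and ``y`` = row; tile windows are half-open rectangles
``[x0, x1) x [y0, y1)`` laid out in row-major order over the padded raster.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .constants import (
    BACKGROUND,
    FINE_CLASSES,
    MERGE_MAP,
    MERGED_CLASSES,
    MAX_BACKGROUND_FRACTION,
    TILE_SIDE,
    BOX_SIDE,
)

__all__ = [
    "TissueLabelMap",
    "Window",
    "PatchGrid",
    "tile_image",
    "background_fraction",
    "filter_patches",
    "merge_classes",
    "boxes_to_mask",
    "drop_lymphocyte_free_patches",
]


@dataclass(frozen=True)
class TissueLabelMap:
    """Integer raster of fine tissue classes with its 3-class merged view.

    Parameters
    ----------
    pixels
        2-D integer array of fine class ids.
    legend
        Mapping of raster value to fine class name. Defaults to the
        package's eight-class vocabulary.
    """

    pixels: np.ndarray
    legend: dict[int, str] = field(default_factory=lambda: dict(FINE_CLASSES))

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"tissue raster must be 2-D, got shape {px.shape}")
        if not np.issubdtype(px.dtype, np.integer):
            raise ValueError("tissue raster must be an integer array")
        present = set(np.unique(px).tolist())
        unknown = present - set(self.legend)
        if unknown:
            raise ValueError(f"pixel values missing from legend: {sorted(unknown)}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def merged_view(self) -> np.ndarray:
        """Deterministic 3-class image of ``pixels`` under the merge map."""
        return merge_classes(self)


@dataclass(frozen=True)
class Window:
    """Half-open tile window with its right/bottom zero-padding widths."""

    x0: int
    y0: int
    x1: int
    y1: int
    pad_right: int = 0
    pad_bottom: int = 0

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0


@dataclass(frozen=True)
class PatchGrid:
    """Row-major tiling of a raster into ``tile_side`` square windows.

    Windows cover the zero-padded raster without overlap or gap; edge
    windows record the zero-padding applied on their right/bottom edges so
    patch-level results can be mapped back to slide coordinates and the
    original raster reassembled bit-exactly.
    """

    shape: tuple[int, int]  # (H, W) of the source raster
    tile_side: int
    windows: tuple[Window, ...]

    def __len__(self) -> int:
        return len(self.windows)

    def extract(self, raster: np.ndarray, window: Window, pad_value=0) -> np.ndarray:
        """Cut one zero-padded ``tile_side`` square patch out of ``raster``."""
        h, w = raster.shape[:2]
        y1 = min(window.y1, h)
        x1 = min(window.x1, w)
        patch = raster[window.y0 : y1, window.x0 : x1]
        if window.pad_right or window.pad_bottom:
            pad = [(0, window.pad_bottom), (0, window.pad_right)]
            pad += [(0, 0)] * (raster.ndim - 2)
            patch = np.pad(patch, pad, constant_values=pad_value)
        return patch

    def reassemble(self, patches: list[np.ndarray]) -> np.ndarray:
        """Invert :func:`tile_image`: stitch patches, cropping the padding."""
        if len(patches) != len(self.windows):
            raise ValueError("patch count does not match window count")
        h, w = self.shape
        extra = patches[0].shape[2:]
        out = np.zeros((h, w) + extra, dtype=patches[0].dtype)
        for patch, win in zip(patches, self.windows):
            core = patch[: win.height - win.pad_bottom, : win.width - win.pad_right]
            out[win.y0 : win.y1 - win.pad_bottom, win.x0 : win.x1 - win.pad_right] = core
        return out


def tile_image(raster: np.ndarray, tile_side: int = TILE_SIDE) -> PatchGrid:
    """Tile a raster into ``tile_side`` squares, zero-padding right/bottom edges.

    Produces ``ceil(H/tile_side) * ceil(W/tile_side)`` windows in row-major
    order. A raster smaller than one tile yields a single window padded up to
    ``tile_side`` — padding only, never interpolation.
    """
    raster = np.asarray(raster)
    if raster.ndim < 2 or raster.size == 0:
        raise ValueError(f"raster must be non-empty and at least 2-D, got shape {raster.shape}")
    if tile_side < 1:
        raise ValueError(f"tile_side must be >= 1, got {tile_side}")
    h, w = raster.shape[:2]
    ny = math.ceil(h / tile_side)
    nx = math.ceil(w / tile_side)
    windows = []
    for iy in range(ny):
        for ix in range(nx):
            x0, y0 = ix * tile_side, iy * tile_side
            x1, y1 = x0 + tile_side, y0 + tile_side
            windows.append(
                Window(x0, y0, x1, y1, pad_right=max(0, x1 - w), pad_bottom=max(0, y1 - h))
            )
    return PatchGrid(shape=(h, w), tile_side=tile_side, windows=tuple(windows))


def background_fraction(
    patch: np.ndarray,
    mode: str = "label",
    *,
    legend: dict[int, str] | None = None,
    brightness_cutoff: float = 0.8,
) -> float:
    """Fraction of a patch that is background.

    ``label`` mode counts pixels whose fine class is ``background`` (raster
    value looked up through ``legend``; defaults to the package vocabulary).
    ``intensity`` mode counts pixels whose grayscale luminance on a [0, 1]
    scale exceeds ``brightness_cutoff`` — a proxy for unstained glass when no
    label raster exists.
    """
    patch = np.asarray(patch)
    if patch.size == 0:
        raise ValueError("empty patch")
    if mode == "label":
        legend = dict(FINE_CLASSES) if legend is None else legend
        bg_ids = [k for k, v in legend.items() if v == "background"]
        if not bg_ids:
            raise ValueError("legend has no 'background' class")
        return float(np.isin(patch, bg_ids).mean())
    if mode == "intensity":
        lum = patch.astype(np.float64)
        if lum.ndim == 3:
            lum = lum @ np.array([0.2126, 0.7152, 0.0722])[: lum.shape[2]]
        if lum.max() > 1.0:
            lum = lum / 255.0
        return float((lum > brightness_cutoff).mean())
    raise ValueError(f"unknown mode {mode!r}; expected 'label' or 'intensity'")


def filter_patches(
    grid: PatchGrid,
    fractions: list[float] | np.ndarray,
    max_bg: float = MAX_BACKGROUND_FRACTION,
) -> PatchGrid:
    """Drop windows whose background fraction *exceeds* ``max_bg``.

    The exclusion rule is strict: a patch at exactly ``max_bg`` is retained.
    ``fractions`` must hold one background fraction per window, in window
    order (see :func:`background_fraction`).
    """
    fractions = np.asarray(fractions, dtype=float)
    if fractions.shape != (len(grid.windows),):
        raise ValueError("need one background fraction per window")
    kept = tuple(w for w, f in zip(grid.windows, fractions) if f <= max_bg)
    return replace(grid, windows=kept)


def merge_classes(fine: TissueLabelMap | np.ndarray) -> np.ndarray:
    """Map an 8-class fine raster onto {other=0, tumor=1, stroma=2}.

    Invasive tumor becomes tumor; tumor-associated and inflamed stroma become
    stroma; every remaining fine class — in-situ tumor, healthy glands,
    necrosis, rest, background — becomes other.  Idempotent on rasters that
    already use the merged labels.
    """
    px = fine.pixels if isinstance(fine, TissueLabelMap) else np.asarray(px_check(fine))
    if isinstance(fine, TissueLabelMap):
        name_of = fine.legend
        lut = {}
        for val, name in name_of.items():
            if name in MERGED_CLASSES.values():  # already merged labels
                lut[val] = {v: k for k, v in MERGED_CLASSES.items()}[name]
            else:
                fid = _fine_id_for(name)
                lut[val] = MERGE_MAP[fid]
    else:
        values = np.unique(px)
        unknown = set(values.tolist()) - set(MERGE_MAP)
        if unknown:
            raise ValueError(f"pixel values not covered by the merge map: {sorted(unknown)}")
        lut = {int(v): MERGE_MAP[int(v)] for v in values}
    out = np.zeros_like(px, dtype=np.uint8)
    for val, merged in lut.items():
        out[px == val] = merged
    return out


def px_check(arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr)
    if arr.ndim != 2 or not np.issubdtype(arr.dtype, np.integer):
        raise ValueError("expected a 2-D integer raster")
    return arr


def _fine_id_for(name: str) -> int:
    from .constants import FINE_NAME_TO_ID

    if name not in FINE_NAME_TO_ID:
        raise ValueError(f"unknown fine class name {name!r}")
    return FINE_NAME_TO_ID[name]


def boxes_to_mask(
    annotations,
    shape: tuple[int, int],
    box_side: int = BOX_SIDE,
) -> np.ndarray:
    """Rasterize point/box annotations into a binary lymphocyte mask.

    Each annotation is painted as a ``box_side`` square centered on its box
    center (top-left = round(center - box_side/2)), clipped to the raster;
    overlapping boxes union.  Accepts a :class:`tilquant.io.CocoAnnotationSet`
    or any iterable of ``[x, y, w, h]`` bboxes.
    """
    h, w = shape
    if h <= 0 or w <= 0:
        raise ValueError(f"shape must be positive, got {shape}")
    mask = np.zeros((h, w), dtype=np.uint8)
    for bbox in _iter_bboxes(annotations):
        bx, by, bw, bh = bbox
        if bw < 0 or bh < 0:
            raise ValueError(f"malformed bbox with negative extent: {bbox}")
        cx = bx + bw / 2.0
        cy = by + bh / 2.0
        x0 = int(round(cx - box_side / 2.0))
        y0 = int(round(cy - box_side / 2.0))
        xa, xb = max(0, x0), min(w, x0 + box_side)
        ya, yb = max(0, y0), min(h, y0 + box_side)
        if xa < xb and ya < yb:
            mask[ya:yb, xa:xb] = 1
    return mask


def _iter_bboxes(annotations):
    records = getattr(annotations, "annotations", annotations)
    for rec in records:
        yield rec["bbox"] if isinstance(rec, dict) else rec


def drop_lymphocyte_free_patches(patches_with_masks):
    """Keep only (patch, mask) pairs whose mask has >= 1 foreground pixel.

    Used when assembling a detection dataset only; evaluation and TIL scoring
    never drop lymphocyte-free patches.
    """
    return [(p, m) for p, m in patches_with_masks if np.asarray(m).any()]
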