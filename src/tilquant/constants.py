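"""Tissue-class vocabulary and the pipeline's numeric constants.

The fine tissue vocabulary follows the eight-class annotation scheme used in
breast-cancer TIL assessment: invasive tumor, tumor-associated stroma, in-situ
tumor, healthy glands, necrosis (non in-situ), inflamed stroma, rest, and
background.  For TIL scoring these are merged into three broad compartments:
tumor, stroma (tumor-associated + inflamed stroma) and other.
"""

from __future__ import annotations

# Fine class ids (8-bit raster values).
INVASIVE_TUMOR = 1
TUMOR_ASSOC_STROMA = 2
IN_SITU_TUMOR = 3
HEALTHY_GLANDS = 4
NECROSIS = 5
INFLAMED_STROMA = 6
REST = 7
BACKGROUND = 0

FINE_CLASSES: dict[int, str] = {
    BACKGROUND: "background",
    INVASIVE_TUMOR: "invasive_tumor",
    TUMOR_ASSOC_STROMA: "tumor_associated_stroma",
    IN_SITU_TUMOR: "in_situ_tumor",
    HEALTHY_GLANDS: "healthy_glands",
    NECROSIS: "necrosis",
    INFLAMED_STROMA: "inflamed_stroma",
    REST: "rest",
}
FINE_NAME_TO_ID: dict[str, int] = {v: k for k, v in FINE_CLASSES.items()}

# Merged (3-class) ids.  Channel order of probability maps is
# (tumor, stroma, other); raster labels use the values below.
MERGED_OTHER = 0
MERGED_TUMOR = 1
MERGED_STROMA = 2

MERGED_CLASSES: dict[int, str] = {
    MERGED_OTHER: "other",
    MERGED_TUMOR: "tumor",
    MERGED_STROMA: "stroma",
}

# Fine -> merged.  Only invasive tumor maps to "tumor"; both stroma variants
# map to "stroma"; everything else (in-situ tumor, glands, necrosis, rest,
# background) is "other".
MERGE_MAP: dict[int, int] = {
    INVASIVE_TUMOR: MERGED_TUMOR,
    TUMOR_ASSOC_STROMA: MERGED_STROMA,
    INFLAMED_STROMA: MERGED_STROMA,
    IN_SITU_TUMOR: MERGED_OTHER,
    HEALTHY_GLANDS: MERGED_OTHER,
    NECROSIS: MERGED_OTHER,
    REST: MERGED_OTHER,
    BACKGROUND: MERGED_OTHER,
}

# Channel order of segmentation probability maps.
SEG_CHANNELS: tuple[str, str, str] = ("tumor", "stroma", "other")
SEG_CHANNEL_TO_MERGED: tuple[int, int, int] = (MERGED_TUMOR, MERGED_STROMA, MERGED_OTHER)

# Pipeline constants (see PipelineConfig for the configurable layer).
TILE_SIDE = 256
MAX_BACKGROUND_FRACTION = 0.65
CANDIDATE_THRESHOLD = 0.1
NMS_DISTANCE = 12.0
MATCH_RADIUS = 8.0
BOX_SIDE = 12
RESOLUTION_UM_PER_PX = 0.5
LYMPHOCYTE_DIAMETER_UM = 8.0
# (8 um / 0.5 um/px) ** 2 = 16 x 16 = 256 px^2
LYMPHOCYTE_AREA_PX = 256
FP_TARGETS = (10.0, 20.0, 50.0, 100.0, 200.0, 300.0)
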