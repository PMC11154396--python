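# Methods

## Pipeline model

`tilquant` treats TIL assessment as a fixed post-processing and evaluation
procedure around two exchangeable learned components. The components enter
only as rasters:

* a segmentation probability map, shape (H, W, 3), channel order
  (tumor, stroma, other), each pixel a probability vector;
* a detection probability map, shape (H, W), values in [0, 1].

Everything downstream is deterministic given those rasters and the
configuration: tiling, background exclusion, candidate extraction, distance
NMS, stroma-restricted scoring, and the metrics.

## Parameters and their defaults

| parameter | default | meaning |
|---|---|---|
| `tile_side` | 256 px | tiling window; edge tiles zero-padded right/bottom |
| `max_bg` | 0.65 | tiles with background fraction strictly above this are excluded |
| `tau` | 0.1 | candidate retention threshold (strictly above) |
| `nms_distance` | 12 px | hard-core suppression radius; `< d` suppresses, `≥ d` keeps |
| `match_radius` | 8 px | TP radius, inclusive |
| `box_side` | 12 px | annotation box stamp around each cell point |
| `fp_targets` | 10…300 | FP/image budgets averaged into the FROC score |
| `resolution_um_per_px` | 0.5 | raster resolution semantics |
| `lymphocyte_diameter_um` | 8 | equivalent cell diameter; with the resolution gives the 16 × 16 = 256 px² footprint |

These defaults are the method's published operating point; the footprint is
derived from diameter and resolution so the 8 µm convention survives a
resolution change.

## Decision rules at the boundaries

Several rules are deliberately pinned and tested:

* a pixel with probability exactly `tau` is **not** a candidate ("exceeding"
  is strict);
* a tile with background fraction exactly `max_bg` **is** retained;
* two detections exactly `nms_distance` apart both survive NMS — two 12-px
  boxes whose centers are 12 apart do not overlap;
* a prediction exactly `match_radius` from a ground-truth cell **is** a true
  positive ("within" is inclusive);
* segmentation argmax ties resolve toward the lower channel index (tumor
  before stroma before other);
* candidate sort ties (equal confidence) break by (y, x) lexicographic
  order, making NMS deterministic across platforms.

Candidates are raw supra-threshold pixels, not connected components; NMS
itself acts as peak selection. A per-component-maximum variant would be a
drop-in replacement behind `extract_candidates`.

Greedy confidence-ordered one-to-one matching (not optimal assignment) is
used for FROC, as is standard practice; the choice is isolated in
`match_detections` so an assignment variant can be swapped in. The FROC
score uses a step rule at each FP budget — best sensitivity among operating
points at or below the budget, zero if none — and never extrapolates.

## Scoring conventions

The score's numerator and denominator are summed across a slide's retained
tiles before one division, so the score is invariant to the tiling as long
as no tile is dropped. Detection-to-stroma membership uses the rounded
center pixel only: the numerator counts lymphocytes, not pixels. Scores are
clipped to [0, 100] — the ratio is an area percentage and can exceed 100
under dense detections; the raw value is kept in the output record so no
information is lost. A slide with zero stroma pixels (or no retained tiles)
gets an undefined score: reporting 0 would assert "no TILs" where the
quantity is meaningless. Undefined slides are dropped pairwise from the
Pearson computation with a logged warning.

Dice with two empty masks is 1.0 (perfect agreement on absence). The
reported Dice "average" is the mean of the tumor and stroma coefficients
only; the "other" coefficient is computed but not averaged in.

## Synthetic cohort generator

The generator emulates the structure of a TIL-assessment cohort — per-slide
tissue maps, stroma-concentrated cell points, model-output rasters, box
annotations, reference scores — at desk scale (slides are 256–4096 px
rasters; the defaults use 320–1024 px in tests).

* **Tissue**: a standard-normal field smoothed at `blob_scale / 4` is
  rank-partitioned at the cumulative class fractions; level sets of a smooth
  field give contiguous regions and the empirical fractions are exact up to
  integer rounding. Default fractions describe a tumor-rich region with one
  quarter background.
* **Cells**: per-class homogeneous Poisson counts with uniform placement,
  thinned hard-core (earlier draw wins) at `min_separation = 12` px. Default
  rates put the densest infiltrate in inflamed stroma, moderate density in
  tumor-associated stroma and scattered cells elsewhere, yielding true TIL
  scores around 10% on default slides. Cohorts scale each slide's rates by a
  factor uniform in [0.3, 2], emulating inter-patient variability and
  guaranteeing score variance for correlation estimates.
* **Segmentation corruption**: i.i.d. Gaussian noise of std `noise_sigma`
  on the one-hot merged truth, optional blur, clip at zero, renormalize.
* **Detection corruption**: each cell contributes a Gaussian bump (radius
  `blur_radius`, default 3 px) peaking at its confidence, combined by
  maximum. `noise_sigma` drives a structured detector-error model:
  confidence jitter `clip(1 − |N(0, σ)|)` (occasionally dropping a cell
  below `tau`), position jitter of std `4σ` px, spurious peaks at Poisson
  rate `σ` per true cell with confidences in [0, σ], plus a low-amplitude
  i.i.d. pixel noise floor (std `σ/20`). Structured corruption was chosen
  over plain i.i.d. pixel noise for the detection map because the candidate
  threshold is a fixed 0.1: i.i.d. noise at σ ≥ 0.1 pushes a sizable
  fraction of *all* pixels above threshold, NMS saturates at its packing
  density, every score clips to 100 and the cohort loses all variance. Real
  detector errors are spatially structured — missed cells, displaced peaks,
  spurious responses — and the structured model degrades the metrics
  gracefully and monotonically in σ.
* **Reference scores** are computed on the noise-free truth by the same
  scoring module and the same tiling/background-exclusion rules the
  prediction side uses, so a perfect detector/segmenter recovers them
  exactly.

Determinism: every stage draws from `numpy.random.default_rng([stage_key,
seed])`, so each output is a pure function of (parameters, seed) and stages
are individually reproducible; cohort slide seeds derive from the cohort
seed the same way.

What the generator does **not** emulate: H&E appearance, stain variation,
nucleus morphology, spatially correlated annotation noise, and the true
spatial statistics of clinical cohorts. Passing tests therefore demonstrate
the correctness of the post-processing, scoring and evaluation machinery —
not the performance of any learned model on real slides.

## Numerical and degenerate-input choices

* Probability-map renormalization clips negatives at zero first; a pixel
  whose channels sum to ~0 falls back to the uniform vector.
* Box stamping anchors at `round(center − box_side/2)` (half-up rounding),
  keeping integer rasters; boxes are clipped at raster edges.
* NMS and hard-core thinning use a spatial hash with cell size equal to the
  radius, giving O(n) behavior with exact equality to the O(n²) greedy
  reference (asserted in tests).
* An empty detection set yields an empty FROC curve, scored 0; a dataset
  with no ground-truth cells makes sensitivity undefined and is an error.
* Pearson requires ≥ 3 defined pairs and non-zero variance on both sides;
  otherwise it raises rather than returning NaN.

## Problem sizes

The test suite and `scripts/acceptance.py` use 20-slide cohorts of 512 px
slides for exact-recovery checks, 5-slide cohorts of 320 px slides across
20 seeds for the noise sweep, and ≤ 500-point candidate sets for oracle
comparisons — sizes at which the whole suite runs in well under a minute
per component while every contract is exercised at full fidelity.

## Known limitations

* The 65% background rule is applied on tissue labels (or an intensity
  proxy with a configurable luminance cutoff of 0.8 for unlabeled tiles);
  which variant a given upstream pipeline used must be matched by the
  caller.
* Whole-slide pyramid formats are out of scope; inputs are flat rasters.
* The in-situ tumor class routes to "other", and the Dice average covers
  tumor and stroma only; pipelines using different conventions need to
  remap before comparison.
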