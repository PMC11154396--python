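# tilquant

Stroma-restricted scoring of tumor-infiltrating lymphocytes (TILs) from
histology rasters, with the full evaluation stack used for TIL-assessment
pipelines in breast-cancer computational pathology.

The density of lymphocytes inside tumor-associated stroma is a prognostic
biomarker in breast cancer. Automated TIL assessment typically couples a
tissue-segmentation model (tumor / stroma / other) with a lymphocyte
detector, then summarizes both into a single per-slide score. `tilquant`
implements everything around the learned models in a model-agnostic way: the
models enter only as probability-map rasters, so any segmentation or
detection backend can be plugged in — or the built-in synthetic generator can
stand in for both, providing exact ground truth for end-to-end testing.

## What it computes

**TIL score.** With detections restricted to the stromal compartment,

```
TILscore = 100 × Σ(TILs × 16 × 16) / Σ(stroma area)
```

where `TILs` is the number of detected lymphocytes whose center pixel lies on
stroma, `16 × 16 = 256 px²` is the footprint of one lymphocyte (8 µm
equivalent diameter at 0.5 µm/px), and the sums run over a slide's retained
256 × 256 px tiles (tiles whose background fraction exceeds 65% are excluded)
before the single division. Scores are clipped to [0, 100]; a slide with no
stroma is reported as undefined, not zero.

**Detection post-processing.** Pixels of the lymphocyte probability map with
probability strictly above 0.1 become candidates; greedy distance-based
non-maximum suppression at 12 px (the annotation box side) keeps one
detection per lymphocyte-sized neighborhood.

**Evaluation.** Per-class Dice for the merged tissue classes (the reported
average is the tumor/stroma mean); FROC — sensitivity vs. average false
positives per image, with a true positive being a detection within 8 px
(inclusive) of an unmatched ground-truth cell, summarized as the mean
sensitivity at FP budgets [10, 20, 50, 100, 200, 300]; and Pearson
correlation between predicted and reference TIL scores.

**Synthetic cohorts.** `tilquant.synthetic` generates desk-scale "slides"
with full ground truth: contiguous eight-class tissue maps (smoothed random
fields cut at class-fraction quantiles), hard-core Poisson lymphocyte points
concentrated in stroma, corrupted probability maps with a single difficulty
knob `noise_sigma`, COCO-style 12 × 12 box annotations, and reference scores
computed on the noise-free truth.

## Worked example

Run the full pipeline — simulate, tile + background-filter, detect, score,
evaluate — on a six-slide cohort with moderate probability-map corruption:

```
$ tilquant run --seed 7 --n-slides 6 --noise-sigma 0.3 --out run/
dice_avg=0.979 froc=0.996 pearson=0.991 over 6 slides
```

The cohort's segmentation is 97.9% Dice (tumor/stroma mean), the detector
reaches 99.6% mean FROC sensitivity, and the predicted TIL scores correlate
at r = 0.991 with the generator's reference scores. `run/til-scores.csv`
holds the per-slide bookkeeping:

```
slide_id,n_tils_in_stroma,stroma_pixels,raw_score,score,defined
slide_000,168,346061,12.427866763374087,12.427866763374087,True
slide_001,125,345959,9.249650970201671,9.249650970201671,True
...
```

e.g. slide_000: 168 stromal lymphocytes × 256 px² over 346,061 stroma px
→ TIL score 12.4. With `--noise-sigma 0` the maps are exact and the pipeline
recovers every reference score bit-for-bit (`pearson=1.000, froc=1.000`).

Library use mirrors the CLI:

```python
from tilquant import PipelineConfig, run_pipeline
report = run_pipeline(PipelineConfig(n_slides=6, noise_sigma=0.3, seed=7,
                                     output_dir="run"))
print(report["metrics"]["pearson_r"])
```

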