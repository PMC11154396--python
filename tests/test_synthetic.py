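"""Tests of the synthetic slide generator: determinism, calibration of class
fractions and point intensities, probability-map contracts, annotations."""

import numpy as np
import pytest
from dataclasses import replace

from tilquant import (
    SynthParams,
    boxes_to_mask,
    dice,
    emit_annotations,
    generate_cohort,
    generate_tissue_map,
    merge_classes,
    prob_to_merged_labels,
    render_probability_maps,
    sample_lymphocyte_points,
)
from tilquant.constants import FINE_NAME_TO_ID
from tilquant.preprocessing import TissueLabelMap


def test_single_class_fractions_degenerate():
    p = SynthParams(width=64, height=64, class_fractions={"background": 1.0}, seed=0)
    t = generate_tissue_map(p)
    assert (t.pixels == FINE_NAME_TO_ID["background"]).all()


def test_tissue_map_deterministic(small_params):
    a = generate_tissue_map(small_params)
    b = generate_tissue_map(small_params)
    np.testing.assert_array_equal(a.pixels, b.pixels)


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        SynthParams(width=0, height=10)
    with pytest.raises(ValueError):
        SynthParams(class_fractions={"background": 0.7})  # does not sum to 1
    with pytest.raises(ValueError):
        SynthParams(noise_sigma=-0.1)


def test_class_fractions_match_request_over_seeds():
    """Empirical per-class area fractions track the requested fractions."""
    fr = {"invasive_tumor": 0.3, "tumor_associated_stroma": 0.4, "background": 0.3}
    counts = {k: [] for k in fr}
    for seed in range(20):
        p = SynthParams(width=256, height=256, class_fractions=fr, seed=seed)
        t = generate_tissue_map(p)
        for name in fr:
            counts[name].append((t.pixels == FINE_NAME_TO_ID[name]).mean())
    for name, want in fr.items():
        assert abs(np.mean(counts[name]) - want) < 0.05


def test_tissue_blobs_are_contiguous(small_params):
    """Level-set construction must yield spatially coherent regions, not salt
    and pepper: the mean class-boundary density stays well below random."""
    t = generate_tissue_map(small_params)
    px = t.pixels
    frac_boundary = (px[:, 1:] != px[:, :-1]).mean()
    assert frac_boundary < 0.10


def test_points_zero_rate_and_determinism(small_params):
    t = generate_tissue_map(small_params)
    p0 = replace(small_params, lympho_rate={k: 0.0 for k in small_params.lympho_rate})
    assert sample_lymphocyte_points(t, p0) == []
    a = sample_lymphocyte_points(t, small_params)
    b = sample_lymphocyte_points(t, small_params)
    assert a == b


def test_points_respect_min_separation(noise_free_slide, small_params):
    truth, _, _ = noise_free_slide
    pts = np.asarray(truth.points, dtype=float)
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    np.fill_diagonal(d2, np.inf)
    assert d2.min() >= small_params.min_separation**2
    h, w = truth.tissue.shape
    assert all(0 <= x < w and 0 <= y < h for x, y in truth.points)


def test_missing_rate_class_rejected(small_params):
    t = generate_tissue_map(small_params)
    bad = replace(small_params, lympho_rate={"background": 0.0})
    with pytest.raises(ValueError, match="missing class"):
        sample_lymphocyte_points(t, bad)


def test_poisson_mean_count():
    """Single-class map, rate r, no thinning: mean count ~= r * area."""
    rate = 5e-4
    p = SynthParams(
        width=128,
        height=128,
        class_fractions={"inflamed_stroma": 1.0},
        lympho_rate={"inflamed_stroma": rate},
        min_separation=0.0,
    )
    t = generate_tissue_map(p)
    expected = rate * 128 * 128  # 8.192
    counts = [
        len(sample_lymphocyte_points(t, replace(p, seed=s))) for s in range(200)
    ]
    se = np.sqrt(expected / 200)
    assert abs(np.mean(counts) - expected) < 3 * se


def test_noise_free_maps_reproduce_truth(noise_free_slide):
    truth, seg, det = noise_free_slide
    np.testing.assert_array_equal(prob_to_merged_labels(seg), truth.tissue.merged_view)
    peak = np.zeros(truth.tissue.shape, dtype=bool)
    for x, y in truth.points:
        peak[y, x] = True
    assert (det[peak] == 1.0).all()


def test_impulse_det_map_without_blur(small_params):
    p = replace(small_params, blur_radius=0.0)
    t = generate_tissue_map(p)
    pts = sample_lymphocyte_points(t, p)
    _, det = render_probability_maps(t, pts, p)
    on = {(x, y) for x, y in pts}
    ys, xs = np.nonzero(det)
    assert {(int(x), int(y)) for x, y in zip(xs, ys)} == on
    assert (det[det > 0] == 1.0).all()


@pytest.mark.parametrize("sigma", [0.0, 0.4])
def test_seg_rows_are_probability_vectors(small_params, sigma):
    p = replace(small_params, noise_sigma=sigma)
    t = generate_tissue_map(p)
    pts = sample_lymphocyte_points(t, p)
    seg, det = render_probability_maps(t, pts, p)
    np.testing.assert_allclose(seg.sum(axis=2), 1.0, atol=1e-6)
    assert seg.min() >= 0
    assert 0.0 <= det.min() and det.max() <= 1.0


def test_seg_dice_degrades_with_noise():
    """Mean Dice of argmax(seg) vs truth is non-increasing in noise_sigma."""
    means = []
    for sigma in (0.0, 0.1, 0.3, 0.6):
        vals = []
        for seed in range(20):
            p = SynthParams(width=96, height=96, noise_sigma=sigma, seed=seed)
            t = generate_tissue_map(p)
            seg, _ = render_probability_maps(t, [], p)
            pred = prob_to_merged_labels(seg)
            gt = t.merged_view
            vals.append(np.mean([dice(pred == c, gt == c) for c in (1, 2)]))
        means.append(np.mean(vals))
    assert all(a >= b - 1e-12 for a, b in zip(means, means[1:]))


def test_annotation_bbox_arithmetic():
    coco = emit_annotations([(100, 50)], box_side=12)
    assert coco.annotations[0]["bbox"] == [94, 44, 12, 12]
    assert len(emit_annotations([])) == 0


def test_annotation_mask_roundtrip_recovers_points():
    """points -> COCO boxes -> mask -> component centroids, within 1 px."""
    from scipy import ndimage

    pts = [(20, 20), (60, 25), (40, 80), (100, 100)]  # boxes never overlap
    coco = emit_annotations(pts, box_side=12)
    mask = boxes_to_mask(coco, (128, 128), box_side=12)
    lab, n = ndimage.label(mask)
    assert n == len(pts)
    centroids = ndimage.center_of_mass(mask, lab, range(1, n + 1))
    got = sorted((cx, cy) for cy, cx in centroids)
    for (gx, gy), (x, y) in zip(got, sorted(pts)):
        assert abs(gx - x) <= 1 and abs(gy - y) <= 1


def test_cohort_single_slide(tmp_path):
    p = SynthParams(width=256, height=256, seed=5)
    manifest = generate_cohort(1, p, tmp_path)
    assert len(manifest["slides"]) == 1
    csv = (tmp_path / "reference-til-scores.csv").read_text().strip().splitlines()
    assert len(csv) == 2  # header + 1 row


def test_cohort_zero_stroma_slide_is_undefined(tmp_path):
    p = SynthParams(
        width=128,
        height=128,
        class_fractions={"invasive_tumor": 1.0},
        seed=5,
    )
    manifest = generate_cohort(1, p, tmp_path)
    assert manifest["slides"][0]["true_til_score"] is None
    import tilquant.io as tio

    scores = tio.read_reference_scores(tmp_path / "reference-til-scores.csv")
    assert scores["slide_000"] is None


def test_cohort_scores_in_range(tmp_path):
    """Full-size cohort: one CSV row per slide, defined scores in [0, 100]."""
    import tilquant.io as tio

    p = SynthParams(width=256, height=256, seed=9)
    manifest = generate_cohort(82, p, tmp_path)
    scores = tio.read_reference_scores(tmp_path / "reference-til-scores.csv")
    assert len(scores) == 82 == len(manifest["slides"])
    defined = [v for v in scores.values() if v is not None]
    assert defined and all(0.0 <= v <= 100.0 for v in defined)
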