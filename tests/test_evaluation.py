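"""Dice, greedy point matching, FROC and Pearson: worked examples, oracle
equivalence and the curve monotonicity invariants."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tilquant import (
    Candidate,
    DetectionSet,
    FROCCurve,
    dice,
    froc_curve,
    froc_score,
    match_detections,
    pearson,
    per_class_dice,
)


def dets(entries):
    """DetectionSet from (x, y, conf), sorted per the package contract."""
    cands = sorted(
        (Candidate(x, y, c) for x, y, c in entries),
        key=lambda c: (-c.confidence, c.y, c.x),
    )
    return DetectionSet(tuple(cands))


class TestDice:
    def test_identical_and_disjoint(self, rng):
        a = rng.random((32, 32)) < 0.3
        assert dice(a, a) == 1.0
        b = np.zeros((4, 4), bool)
        b[0, 0] = True
        c = np.zeros((4, 4), bool)
        c[3, 3] = True
        assert dice(b, c) == 0.0

    def test_set_cardinality_example(self):
        p = np.zeros(200, bool)
        g = np.zeros(200, bool)
        p[:100] = True  # |P| = 100
        g[50:150] = True  # |G| = 100, overlap 50
        assert dice(p.reshape(10, 20), g.reshape(10, 20)) == 0.5

    def test_both_empty_is_perfect_agreement(self):
        assert dice(np.zeros((8, 8)), np.zeros((8, 8))) == 1.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            dice(np.zeros((4, 4)), np.zeros((5, 5)))


class TestPerClassDice:
    def test_perfect_prediction(self, rng):
        gt = rng.integers(0, 3, (32, 32)).astype(np.uint8)
        out = per_class_dice(gt, gt)
        assert out == {"tumor": 1.0, "stroma": 1.0, "other": 1.0, "average": 1.0}

    def test_average_is_tumor_stroma_mean(self, rng):
        pred = rng.integers(0, 3, (64, 64)).astype(np.uint8)
        gt = rng.integers(0, 3, (64, 64)).astype(np.uint8)
        out = per_class_dice(pred, gt)
        assert out["average"] == pytest.approx((out["tumor"] + out["stroma"]) / 2)

    def test_matches_binary_oracle(self, rng):
        for _ in range(20):
            pred = rng.integers(0, 3, (48, 48)).astype(np.uint8)
            gt = rng.integers(0, 3, (48, 48)).astype(np.uint8)
            out = per_class_dice(pred, gt)
            for cid, name in [(1, "tumor"), (2, "stroma"), (0, "other")]:
                p, g = pred == cid, gt == cid
                inter = (p & g).sum()
                want = 1.0 if p.sum() + g.sum() == 0 else 2 * inter / (p.sum() + g.sum())
                assert out[name] == pytest.approx(want)


def greedy_match_oracle(pred_pts, gt_pts, radius):
    """Literal restatement of the matching rule for tiny inputs."""
    taken = set()
    tp = 0
    for px, py in pred_pts:  # already confidence-sorted
        best, best_d = None, None
        for gi, (gx, gy) in enumerate(gt_pts):
            if gi in taken:
                continue
            d = np.hypot(px - gx, py - gy)
            if d <= radius and (best_d is None or d < best_d):
                best, best_d = gi, d
        if best is not None:
            taken.add(best)
            tp += 1
    return tp


class TestMatchDetections:
    def test_inside_inclusive_radius(self):
        res = match_detections(dets([(7, 0, 0.9)]), [(0, 0)], 8)
        assert (res.tp, res.fp, res.fn) == (1, 0, 0)

    def test_exactly_at_radius_is_tp(self):
        res = match_detections(dets([(8, 0, 0.9)]), [(0, 0)], 8)
        assert res.tp == 1

    def test_outside_radius(self):
        res = match_detections(dets([(9, 0, 0.9)]), [(0, 0)], 8)
        assert (res.tp, res.fp, res.fn) == (0, 1, 1)

    def test_confidence_order_claims_first(self):
        res = match_detections(dets([(3, 0, 0.9), (5, 0, 0.8)]), [(0, 0)], 8)
        assert (res.tp, res.fp) == (1, 1)
        assert res.pairs[0][0] == 0  # the 0.9 detection holds the match

    def test_counts_are_consistent(self, rng):
        pred = dets([(int(x), int(y), float(c)) for x, y, c in
                     np.c_[rng.integers(0, 50, (30, 2)), rng.random(30)]])
        gt = rng.integers(0, 50, (20, 2))
        res = match_detections(pred, gt, 8)
        assert res.tp == len(res.pairs)
        assert res.tp + res.fn == len(gt)
        assert res.tp + res.fp == len(pred)
        assert all(d <= 8 for _, _, d in res.pairs)

    def test_matches_exhaustive_oracle_small(self, rng):
        for _ in range(50):
            n_p, n_g = rng.integers(0, 8), rng.integers(0, 8)
            pred_pts = rng.integers(0, 30, (n_p, 2)).astype(float)
            confs = -np.sort(-rng.random(n_p))
            gt = rng.integers(0, 30, (n_g, 2)).astype(float)
            ds = DetectionSet(tuple(
                Candidate(float(x), float(y), float(c))
                for (x, y), c in zip(pred_pts, confs)
            ))
            res = match_detections(ds, gt, 8)
            assert res.tp == greedy_match_oracle(pred_pts, gt, 8)


def froc_oracle(per_image, radius):
    """Brute-force per-threshold recomputation of the whole curve."""
    confs = sorted(
        {d.confidence for ds, _ in per_image for d in ds}, reverse=True
    )
    n_gt = sum(len(g) for _, g in per_image)
    pts = []
    for t in confs:
        tp = fp = 0
        for ds, gt in per_image:
            sub = DetectionSet(tuple(d for d in ds if d.confidence >= t))
            r = match_detections(sub, gt, radius)
            tp, fp = tp + r.tp, fp + r.fp
        pts.append((t, fp / len(per_image), tp / n_gt))
    return pts


class TestFROC:
    def test_perfect_detector(self):
        per_image = [(dets([(0, 0, 1.0), (30, 0, 1.0)]), [(0, 0), (30, 0)])]
        curve = froc_curve(per_image)
        assert curve.points == ((1.0, 0.0, 1.0),)
        assert froc_score(curve) == 1.0

    def test_empty_detector(self):
        per_image = [(dets([]), [(0, 0)])]
        curve = froc_curve(per_image)
        assert len(curve) == 0 and froc_score(curve) == 0.0

    def test_worked_two_image_example(self):
        """Interleaved TP/FP confidences produce the expected staircase."""
        img1 = (dets([(0, 0, 1.0), (100, 100, 0.9)]), [(0, 0), (50, 0)])
        img2 = (dets([(50, 1, 0.8), (200, 200, 0.7)]), [(0, 0), (50, 0)])
        curve = froc_curve([img1, img2])
        assert curve.points == (
            (1.0, 0.0, 0.25),
            (0.9, 0.5, 0.25),
            (0.8, 0.5, 0.5),
            (0.7, 1.0, 0.5),
        )

    def test_zero_ground_truth_rejected(self):
        with pytest.raises(ValueError, match="sensitivity undefined"):
            froc_curve([(dets([(0, 0, 0.5)]), [])])

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(30):
            n_img = int(rng.integers(1, 6))
            per_image = []
            for _ in range(n_img):
                n_d, n_g = rng.integers(0, 30), rng.integers(1, 30)
                entries = [
                    (int(x), int(y), float(np.round(c, 2)))
                    for x, y, c in np.c_[rng.integers(0, 80, (n_d, 2)), rng.random(n_d)]
                ]
                per_image.append((dets(entries), rng.integers(0, 80, (n_g, 2))))
            curve = froc_curve(per_image)
            assert list(curve.points) == froc_oracle(per_image, 8)

    def test_step_rule_score(self):
        curve = FROCCurve(
            (
                (0.9, 5.0, 0.6),
                (0.5, 20.0, 0.8),
                (0.3, 50.0, 0.9),
                (0.1, 400.0, 0.95),
            )
        )
        # targets 10 -> 0.6; 20 -> 0.8; 50/100/200/300 -> 0.9; never the 400-FP point
        assert froc_score(curve) == pytest.approx((0.6 + 0.8 + 4 * 0.9) / 6)

    def test_no_point_under_first_target_scores_zero(self):
        curve = FROCCurve(((0.5, 1000.0, 1.0),))
        assert froc_score(curve) == 0.0


@settings(deadline=None, max_examples=40, derandomize=True)
@given(data=st.data())
def test_froc_curve_monotone_invariants(data):
    """As the threshold drops, FP/image and sensitivity never decrease."""
    n_img = data.draw(st.integers(1, 4))
    per_image = []
    for i in range(n_img):
        entries = data.draw(
            st.lists(
                st.tuples(st.integers(0, 60), st.integers(0, 60), st.floats(0.01, 1.0)),
                max_size=25,
            ),
            label=f"dets{i}",
        )
        gt = data.draw(
            st.lists(st.tuples(st.integers(0, 60), st.integers(0, 60)),
                     min_size=1, max_size=10),
            label=f"gt{i}",
        )
        per_image.append((dets(entries), np.array(gt, dtype=float)))
    curve = froc_curve(per_image)
    fps = [p[1] for p in curve.points]
    sens = [p[2] for p in curve.points]
    assert all(a <= b + 1e-12 for a, b in zip(fps, fps[1:]))
    assert all(a <= b + 1e-12 for a, b in zip(sens, sens[1:]))
    assert all(0.0 <= s <= 1.0 for s in sens)


class TestPearson:
    def test_identity_and_sign_flip(self):
        v = [10.0, 20.0, 30.0, 40.0]
        assert pearson(v, v) == pytest.approx(1.0)
        assert pearson(v, [-x for x in v]) == pytest.approx(-1.0)

    def test_linear_pair(self):
        assert pearson([1, 2, 3, 4, 5], [2, 4, 6, 8, 10]) == pytest.approx(1.0)

    def test_undefined_pairs_dropped(self):
        r = pearson([1.0, None, 2.0, 3.0, 4.0], [2.0, 50.0, 4.0, 6.0, None])
        assert r == pytest.approx(1.0)  # only the 3 complete linear pairs remain

    def test_too_few_pairs(self):
        with pytest.raises(ValueError, match=">= 3"):
            pearson([1.0, 2.0], [1.0, 2.0])

    def test_zero_variance(self):
        with pytest.raises(ValueError, match="zero variance"):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
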