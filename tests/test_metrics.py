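"""Scalar metrics and averaging combinators against hand-derived values."""

import numpy as np
import pytest

from segscore.errors import EmptyDatasetError, MissingConfidenceError
from segscore.matching import ConfusionCounts, MatchResult, match_instances
from segscore.metrics import (
    PRCurve,
    ap1,
    build_pr_curve,
    digits_score,
    f1_score,
    image_average,
    panoptic_quality,
    precision,
    recall,
    simple_metrics,
    threat_score,
    threshold_average,
    class_average,
)

from conftest import grid_gt, jitter_pred, random_confidences
from oracles import envelope_area, pr_points


def counts(tp, fp, fn):
    return ConfusionCounts(tp, fp, fn)


class TestSimpleMetrics:
    @pytest.mark.parametrize("c, expected", [
        (counts(1, 1, 1), {"precision": 0.5, "recall": 0.5, "f1": 0.5,
                           "threat_score": 1 / 3}),
        (counts(5, 0, 0), {"precision": 1.0, "recall": 1.0, "f1": 1.0,
                           "threat_score": 1.0}),
        (counts(0, 0, 0), {"precision": 1.0, "recall": 1.0, "f1": 1.0,
                           "threat_score": 1.0}),  # empty-vs-empty is perfect
        (counts(9, 1, 1), {"precision": 0.9, "recall": 0.9, "f1": 9 / 10,
                           "threat_score": 9 / 11}),
    ])
    def test_printed_formula_values(self, c, expected):
        got = simple_metrics(c)
        for name, val in expected.items():
            assert got[name] == pytest.approx(val, abs=1e-15)

    def test_empty_convention_is_configurable(self):
        assert threat_score(counts(0, 0, 0), empty_score=0.0) == 0.0
        assert precision(counts(0, 0, 0), empty_score=0.5) == 0.5

    def test_degenerate_directions(self):
        # empty gt, nonempty pred: precision 0; empty pred, nonempty gt: recall 0
        assert precision(counts(0, 3, 0)) == 0.0
        assert recall(counts(0, 3, 0)) == 0.0  # non-empty image: 0/0 scores 0
        assert recall(counts(0, 0, 2)) == 0.0
        assert precision(counts(0, 0, 2)) == 0.0

    def test_f1_is_monotone_transform_of_threat_score(self, rng):
        # F1 = 2 TS / (1 + TS): algebraic identity behind the deterministic
        # rank relation between the two scores at a fixed threshold
        for _ in range(200):
            c = counts(*(int(x) for x in rng.integers(0, 30, size=3)))
            ts = threat_score(c)
            assert f1_score(c) == pytest.approx(2 * ts / (1 + ts), abs=1e-12)

    def test_digits_is_precision_times_recall(self):
        assert digits_score(counts(1, 1, 1)) == pytest.approx(0.25)
        assert digits_score(counts(5, 0, 0)) == 1.0
        assert digits_score(counts(0, 3, 2)) == 0.0

    def test_scores_bounded(self, rng):
        for _ in range(100):
            c = counts(*(int(x) for x in rng.integers(0, 20, size=3)))
            for v in simple_metrics(c).values():
                assert 0.0 <= v <= 1.0


class TestPanopticQuality:
    def _mr(self, pairs, n_fp=0, n_fn=0):
        return MatchResult(0.5, tuple(pairs),
                           frozenset(range(1000, 1000 + n_fn)),
                           frozenset(range(2000, 2000 + n_fp)))

    def test_single_pair_returns_its_iou(self):
        assert panoptic_quality(self._mr([(1, 1, 0.8)])) == pytest.approx(0.8)

    def test_perfect_prediction_is_one(self):
        m = self._mr([(i, i, 1.0) for i in range(5)])
        assert panoptic_quality(m) == 1.0

    def test_detection_penalty(self):
        assert panoptic_quality(self._mr([], n_fp=1, n_fn=1)) == 0.0
        # one pair iou .8 with 1 fp, 1 fn: 0.8 / (1 + 1) = 0.4
        assert panoptic_quality(self._mr([(1, 1, 0.8)], 1, 1)) == pytest.approx(0.4)

    def test_empty_everything_is_zero(self):
        assert panoptic_quality(self._mr([])) == 0.0

    def test_pq_never_exceeds_f1(self, rng):
        # each matched IoU <= 1, so PQ <= TP / (TP + (FP+FN)/2), which is
        # exactly F1; PQ factorises as mean-matched-IoU x F1
        for _ in range(30):
            gt = grid_gt(rng, n_objects=6)
            pred = jitter_pred(rng, gt, max_shift=1)
            m = match_instances(gt, pred, 0.5)
            c_tp, c_fp, c_fn = len(m.pairs), len(m.unmatched_pred), len(m.unmatched_gt)
            f1 = (2 * c_tp / (2 * c_tp + c_fp + c_fn)
                  if c_tp + c_fp + c_fn else 1.0)
            assert panoptic_quality(m) <= f1 + 1e-12


class TestPRCurveAndAP1:
    def _toy(self):
        """2 gt objects; preds at conf 0.9 (TP), 0.8 (FP), 0.7 (TP)."""
        gt = np.zeros((4, 12), int)
        gt[0:2, 0:2] = 1
        gt[0:2, 4:6] = 2
        pred = np.zeros((4, 12), int)
        pred[0:2, 0:2] = 1   # TP
        pred[0:2, 8:10] = 2  # FP
        pred[0:2, 4:6] = 3   # TP
        return gt, pred, {1: 0.9, 2: 0.8, 3: 0.7}

    def test_hand_enumerated_curve(self):
        curve = build_pr_curve([self._toy()], 0.5)
        assert curve.points == ((0.5, 1.0), (0.5, 0.5), (1.0, pytest.approx(2 / 3)))

    def test_all_points_area_is_five_sixths(self):
        assert ap1(build_pr_curve([self._toy()], 0.5)) == pytest.approx(5 / 6)

    def test_perfect_curve_is_one(self):
        gt, _, _ = self._toy()
        curve = build_pr_curve([(gt, gt, {1: 0.9, 2: 0.8})], 0.5)
        assert all(p == 1.0 for _, p in curve.points)
        assert ap1(curve) == 1.0

    def test_no_predictions_scores_zero(self):
        gt, _, _ = self._toy()
        curve = build_pr_curve([(gt, np.zeros_like(gt), {})], 0.5)
        assert curve.points == ()
        assert ap1(curve) == 0.0

    def test_missing_confidence_raises(self):
        gt, pred, conf = self._toy()
        del conf[2]
        with pytest.raises(MissingConfidenceError):
            build_pr_curve([(gt, pred, conf)], 0.5)
        with pytest.raises(MissingConfidenceError):
            build_pr_curve([(gt, pred, None)], 0.5)

    def test_recall_nondecreasing_along_curve(self, rng):
        for _ in range(20):
            gt = grid_gt(rng, n_objects=6)
            pred = jitter_pred(rng, gt)
            curve = build_pr_curve([(gt, pred, random_confidences(rng, pred))], 0.5)
            recs = [r for r, _ in curve.points]
            assert recs == sorted(recs)

    def test_ap1_matches_bruteforce_envelope_on_random_sets(self, rng):
        for _ in range(30):
            images = []
            scored, n_gt = [], 0
            for _ in range(2):
                gt = grid_gt(rng, shape=(32, 32), n_objects=4, cell=8)
                pred = jitter_pred(rng, gt)
                conf = random_confidences(rng, pred)
                images.append((gt, pred, conf))
            got = ap1(build_pr_curve(images, 0.5))
            # independent route: exhaustive cutoffs + exact envelope area
            from oracles import ap1_bruteforce

            assert got == pytest.approx(ap1_bruteforce(images, 0.5), abs=1e-12)

    def test_coco_101_close_to_exact_area(self):
        exact = ap1(build_pr_curve([self._toy()], 0.5), "all_points")
        sampled = ap1(build_pr_curve([self._toy()], 0.5), "coco_101")
        assert abs(exact - sampled) < 0.02

    def test_raw_integration_flag(self):
        # without the envelope the precision dip at the FP is integrated
        curve = PRCurve(points=((0.5, 1.0), (0.5, 0.5), (1.0, 2 / 3)))
        assert ap1(curve, envelope=False) == pytest.approx(0.5 * 1.0 + 0.5 * (2 / 3))


class TestCombinators:
    def test_threshold_average_is_arithmetic_mean(self):
        scores = {0.5: 1.0, 0.75: 0.5}
        assert threshold_average(scores.__getitem__, [0.5, 0.75]) == 0.75
        assert threshold_average(lambda t: 0.42, [0.5]) == 0.42
        ten = [round(0.5 + 0.05 * k, 2) for k in range(10)]
        assert threshold_average(lambda t: 0.3, ten) == pytest.approx(0.3)

    def test_empty_threshold_range_raises(self):
        with pytest.raises(EmptyDatasetError):
            threshold_average(lambda t: 1.0, [])

    def test_image_average_worked_example(self):
        per_image = [counts(9, 1, 1), counts(0, 0, 1)]
        avg = image_average(lambda c: threat_score(c), per_image)
        assert avg == pytest.approx(9 / 22)
        pooled = counts(9, 1, 2)
        assert threat_score(pooled) == pytest.approx(3 / 4)

    def test_single_image_passthrough(self):
        assert image_average(lambda c: threat_score(c), [counts(3, 1, 0)]) == 0.75

    def test_class_average(self):
        aps = {"nucleus": 1.0, "mitosis": 0.5}
        labels = {k: k for k in aps}  # base is applied to each class's input
        assert class_average(aps.__getitem__, labels) == 0.75
        assert class_average(aps.__getitem__, {"nucleus": "nucleus"}) == 1.0
        with pytest.raises(EmptyDatasetError):
            class_average(lambda x: 1.0, {})

    def test_averages_bounded_by_extremes(self, rng):
        vals = rng.uniform(0, 1, size=7).tolist()
        got = image_average(lambda v: v, vals)
        assert min(vals) <= got <= max(vals)
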