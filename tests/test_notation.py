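"""The explicit metric notation: grammar round trips and dispatch."""

import numpy as np
import pytest

from segscore.dataset import ImagePair
from segscore.errors import EmptyDatasetError, MissingConfidenceError, SpecParseError
from segscore.notation import (
    BASE_METRICS,
    MetricSpec,
    ThresholdRange,
    evaluate_spec,
    format_spec,
    parse_spec,
)

from conftest import grid_gt, jitter_pred, random_confidences


def blocks_dataset():
    """Two-image dataset with object counts 10+1: image A counts (9,1,1),
    image B counts (0,0,1) — the aggregation-divergence worked example."""
    def make(n_gt, n_tp, n_fp):
        w = 4 * (n_gt + n_fp + 1)
        g = np.zeros((4, w), int)
        p = np.zeros((4, w), int)
        for i in range(n_gt):
            g[0:2, 4 * i:4 * i + 2] = i + 1
        for i in range(n_tp):
            p[0:2, 4 * i:4 * i + 2] = i + 1
        for i in range(n_fp):
            p[0:2, 4 * (n_gt + i):4 * (n_gt + i) + 2] = n_tp + i + 1
        return ImagePair(gt=g, pred=p,
                         confidences={int(i): 1.0 for i in np.unique(p) if i > 0})
    return [make(10, 9, 1), make(1, 0, 0)]


class TestThresholdRange:
    def test_canonical_coco_range_is_exact(self):
        tr = ThresholdRange(start=0.5, stop=0.95, step=0.05)
        assert tr.values == (0.5, 0.55, 0.6, 0.65, 0.7, 0.75, 0.8, 0.85, 0.9, 0.95)
        assert tr.values[-1] == 0.95  # grid rounding: 0.5 + 9*0.05 exactly

    def test_single_threshold_is_degenerate_range(self):
        tr = ThresholdRange.single(0.5)
        assert tr.values == (0.5,)
        assert tr.is_single

    def test_partial_step_stops_before_stop(self):
        assert ThresholdRange(0.5, 0.95, 0.2).values == (0.5, 0.7, 0.9)

    @pytest.mark.parametrize("kwargs", [
        dict(start=-0.1, stop=0.5, step=0.1),
        dict(start=0.5, stop=1.0, step=0.1),
        dict(start=0.6, stop=0.5, step=0.1),
        dict(start=0.5, stop=0.9, step=0.0),
    ])
    def test_invalid_ranges_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ThresholdRange(**kwargs)


class TestParseFormat:
    def test_aggregated_threat_score_notation(self):
        spec = parse_spec("TS_agg^0.5:0.05:0.95")
        assert spec.base == "TS" and spec.mode == "agg"
        assert spec.thresholds == ThresholdRange(0.5, 0.95, 0.05)
        assert spec.level == "object"
        assert format_spec(spec) == "TS_agg^0.5:0.05:0.95"

    def test_averaged_f1_notation(self):
        spec = parse_spec("F1_avg^0.5")
        assert spec.base == "F1" and spec.mode == "avg"
        assert spec.thresholds.is_single and spec.thresholds.start == 0.5
        assert format_spec(spec) == "F1_avg^0.5"

    def test_bare_ap_and_map_rejected_with_guidance(self):
        for bad in ("AP_agg^0.5", "mAP_avg^0.5:0.05:0.95"):
            with pytest.raises(SpecParseError, match="ambiguous"):
                parse_spec(bad)

    def test_unknown_base_lists_valid_names(self):
        with pytest.raises(SpecParseError, match="TS"):
            parse_spec("dice_agg^0.5")

    def test_threshold_part_required(self):
        with pytest.raises(SpecParseError, match="explicit"):
            parse_spec("TS_agg")

    def test_mode_required(self):
        with pytest.raises(SpecParseError, match="agg"):
            parse_spec("TS^0.5")

    def test_malformed_range(self):
        with pytest.raises(SpecParseError, match="malformed"):
            parse_spec("TS_agg^0.5:0.05")
        with pytest.raises(SpecParseError, match="malformed"):
            parse_spec("TS_agg^abc")

    def test_whitespace_insensitive(self):
        assert parse_spec(" TS_agg ^ 0.5 : 0.05 : 0.95 ") == \
            parse_spec("TS_agg^0.5:0.05:0.95")

    def test_iou_alias_accepted(self):
        assert parse_spec("TS_agg@IoU=0.5") == parse_spec("TS_agg^0.5")
        assert parse_spec("TS_agg@(IoU=0.5:0.05:0.95)") == \
            parse_spec("TS_agg^0.5:0.05:0.95")

    def test_pixel_prefix(self):
        spec = parse_spec("px:F1_agg^0.5")
        assert spec.level == "pixel"
        assert format_spec(spec) == "px:F1_agg^0.5"

    def test_pixel_level_only_for_simple_metrics(self):
        with pytest.raises(SpecParseError, match="pixel"):
            parse_spec("px:PQ_agg^0.5")

    @pytest.mark.parametrize("base", BASE_METRICS)
    @pytest.mark.parametrize("mode", ["agg", "avg"])
    @pytest.mark.parametrize("thr", ["0.5", "0.9", "0.5:0.05:0.95", "0.3:0.1:0.7"])
    def test_roundtrip_over_canonical_grammar(self, base, mode, thr):
        s = f"{base}_{mode}^{thr}"
        spec = parse_spec(s)
        assert format_spec(spec) == s
        assert parse_spec(format_spec(spec)) == spec


class TestEvaluateSpec:
    def test_perfect_prediction_scores_one_everywhere(self, rng):
        gt = grid_gt(rng, n_objects=5)
        conf = {int(i): 1.0 for i in np.unique(gt) if i > 0}
        ds = [ImagePair(gt=gt, pred=gt.copy(), confidences=conf)]
        for base in BASE_METRICS:
            for mode in ("agg", "avg"):
                score = evaluate_spec(f"{base}_{mode}^0.5:0.05:0.95", ds)
                assert score == pytest.approx(1.0), (base, mode)

    def test_dispatch_totality_on_imperfect_data(self, rng):
        # every catalogued variant must be reachable and lie in [0, 1]
        gt = grid_gt(rng, n_objects=6)
        pred = jitter_pred(rng, gt)
        ds = [ImagePair(gt=gt, pred=pred,
                        confidences=random_confidences(rng, pred))]
        for base in BASE_METRICS:
            for mode in ("agg", "avg"):
                score = evaluate_spec(f"{base}_{mode}^0.5", ds)
                assert 0.0 <= score <= 1.0, (base, mode)
        for base in ("TS", "F1", "precision", "recall"):
            score = evaluate_spec(f"px:{base}_agg^0.5", ds)
            assert 0.0 <= score <= 1.0

    def test_aggregation_divergence_worked_example(self):
        ds = blocks_dataset()
        assert evaluate_spec("TS_agg^0.5", ds) == pytest.approx(3 / 4, abs=1e-15)
        assert evaluate_spec("TS_avg^0.5", ds) == pytest.approx(9 / 22, abs=1e-15)

    def test_map4_digits_on_pooled_counts(self):
        g = np.zeros((4, 16), int)
        p = np.zeros((4, 16), int)
        g[0:2, 0:2] = 1; p[0:2, 0:2] = 1          # TP
        p[0:2, 4:6] = 2                            # FP
        g[0:2, 8:10] = 2                           # FN
        score = evaluate_spec("mAP4_agg^0.5", [ImagePair(gt=g, pred=p)])
        assert score == pytest.approx(1 / 4)  # precision 1/2 x recall 1/2

    def test_ap2_is_threat_score(self, rng):
        gt = grid_gt(rng, n_objects=5)
        pred = jitter_pred(rng, gt)
        ds = [ImagePair(gt=gt, pred=pred)]
        assert evaluate_spec("AP2_agg^0.5", ds) == evaluate_spec("TS_agg^0.5", ds)

    def test_ranged_ap1_equals_ap4(self, rng):
        gt = grid_gt(rng, n_objects=5)
        pred = jitter_pred(rng, gt)
        ds = [ImagePair(gt=gt, pred=pred,
                        confidences=random_confidences(rng, pred))]
        r = "0.5:0.05:0.95"
        assert evaluate_spec(f"AP1_agg^{r}", ds) == \
            pytest.approx(evaluate_spec(f"AP4_agg^{r}", ds), abs=1e-15)

    def test_curve_metrics_require_confidences(self, rng):
        gt = grid_gt(rng, n_objects=3)
        ds = [ImagePair(gt=gt, pred=gt.copy())]
        with pytest.raises(MissingConfidenceError):
            evaluate_spec("AP1_agg^0.5", ds)

    def test_empty_dataset_rejected(self):
        with pytest.raises(EmptyDatasetError):
            evaluate_spec("TS_agg^0.5", [])

    def test_class_average_over_two_classes(self, rng):
        # one class predicted perfectly, the other completely missed
        gt = grid_gt(rng, n_objects=4)
        ids = [int(i) for i in np.unique(gt) if i > 0]
        half = set(ids[:2])
        classes = {i: ("a" if i in half else "b") for i in ids}
        pred = np.where(np.isin(gt, list(half)), gt, 0)
        ds = [ImagePair(gt=gt, pred=pred,
                        confidences={i: 1.0 for i in half},
                        gt_classes=classes,
                        pred_classes={i: "a" for i in half})]
        # class a: AP1 = 1; class b: no predictions -> AP1 = 0
        assert evaluate_spec("mAP1_agg^0.5", ds) == pytest.approx(0.5)

    def test_strict_flag_at_exact_half_iou(self):
        g = np.zeros((4, 8), int); g[0:2, 0:2] = 1
        p = np.zeros((4, 8), int); p[0:1, 0:2] = 1  # IoU exactly 0.5
        ds = [ImagePair(gt=g, pred=p)]
        strict = MetricSpec("TS", "agg", ThresholdRange.single(0.5))
        loose = MetricSpec("TS", "agg", ThresholdRange.single(0.5),
                           strict_iou=False)
        assert evaluate_spec(strict, ds) == 0.0
        assert evaluate_spec(loose, ds) == 1.0
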