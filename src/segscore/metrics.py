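"""Scalar evaluation metrics for instance segmentation and detection.

The object-level metrics all consume the same atoms: confusion counts
(TP, FP, FN) from IoU-threshold matching, and, for the matched pairs, their
IoU values.  The module provides

* the simple confusion metrics — precision, recall, F1, threat score
  TP/(TP+FP+FN) (the score bioimage competitions often mislabel "AP");
* panoptic quality, PQ = (sum of matched IoUs) / (TP + (FP+FN)/2), which
  couples segmentation quality with recognition quality;
* the classical average precision AP1 = area under the precision-recall
  curve swept over prediction-confidence cutoffs, with PASCAL all-points or
  COCO 101-point interpolation;
* the "Digits score", precision x recall;
* combinators that average a base metric over IoU thresholds, over images,
  or over classes — the three axes along which the many coexisting "AP" and
  "mAP" interpretations differ.

Degenerate counts follow a stated convention: an image where both ground
truth and prediction are empty scores ``empty_score`` (default 1.0 —
predicting nothing when there is nothing is perfect); any other 0/0
denominator scores 0.  Both choices matter for image-averaged scores and
are therefore explicit parameters, never silent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .errors import EmptyDatasetError, MissingConfidenceError
from .matching import (
    ConfusionCounts,
    MatchResult,
    instance_ids,
    match_by_confidence,
)

__all__ = [
    "PRCurve",
    "simple_metrics",
    "precision",
    "recall",
    "f1_score",
    "threat_score",
    "digits_score",
    "panoptic_quality",
    "build_pr_curve",
    "ap1",
    "threshold_average",
    "image_average",
    "class_average",
    "SIMPLE_METRIC_NAMES",
]

SIMPLE_METRIC_NAMES = ("precision", "recall", "f1", "threat_score")


# ---------------------------------------------------------------------------
# Confusion-count metrics
# ---------------------------------------------------------------------------

def _ratio(num: float, den: float, c: ConfusionCounts, empty_score: float) -> float:
    if den > 0:
        return num / den
    # 0/0: all-empty image is "perfect by convention", anything else scores 0
    return empty_score if (c.tp + c.fp + c.fn) == 0 else 0.0


def precision(c: ConfusionCounts, empty_score: float = 1.0) -> float:
    """TP / (TP + FP): what fraction of predictions is correct."""
    return _ratio(c.tp, c.tp + c.fp, c, empty_score)


def recall(c: ConfusionCounts, empty_score: float = 1.0) -> float:
    """TP / (TP + FN): what fraction of objects is found (sensitivity)."""
    return _ratio(c.tp, c.tp + c.fn, c, empty_score)


def f1_score(c: ConfusionCounts, empty_score: float = 1.0) -> float:
    """2·TP / (2·TP + FP + FN), the harmonic mean of precision and recall."""
    return _ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn, c, empty_score)


def threat_score(c: ConfusionCounts, empty_score: float = 1.0) -> float:
    """TP / (TP + FP + FN) — object-level Jaccard / critical success index."""
    return _ratio(c.tp, c.tp + c.fp + c.fn, c, empty_score)


def digits_score(c: ConfusionCounts, empty_score: float = 1.0) -> float:
    """Precision x recall (the "Digits score")."""
    return precision(c, empty_score) * recall(c, empty_score)


_SIMPLE_FNS: dict[str, Callable[..., float]] = {
    "precision": precision,
    "recall": recall,
    "f1": f1_score,
    "threat_score": threat_score,
}


def simple_metrics(
    c: ConfusionCounts, empty_score: float = 1.0
) -> dict[str, float]:
    """Evaluate precision, recall, F1 and threat score on one set of counts."""
    return {name: fn(c, empty_score) for name, fn in _SIMPLE_FNS.items()}


def panoptic_quality(m: MatchResult) -> float:
    """PQ = (sum of matched IoUs) / (TP + (FP + FN) / 2).

    The numerator rewards boundary quality of the matched pairs, the
    denominator penalises missed and spurious detections.  A match result
    with no instances at all (zero denominator) scores 0.
    """
    tp = len(m.pairs)
    denom = tp + (len(m.unmatched_pred) + len(m.unmatched_gt)) / 2.0
    if denom == 0:
        return 0.0
    return sum(iou for _, _, iou in m.pairs) / denom


# ---------------------------------------------------------------------------
# Precision-recall curves and AP1
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PRCurve:
    """A precision-recall curve: ``(recall, precision)`` points ordered by
    descending confidence cutoff, plus the cutoff at each point.  Recall is
    non-decreasing along the sequence."""

    points: tuple[tuple[float, float], ...]
    cutoffs: tuple[float, ...] = ()


def build_pr_curve(
    images: Sequence[tuple[np.ndarray, np.ndarray, Mapping[int, float]]],
    threshold: float,
    strict: bool = True,
) -> PRCurve:
    """Build a dataset-pooled PR curve at one IoU threshold.

    ``images`` is a sequence of ``(gt_mask, pred_mask, confidences)``
    triples; every predicted instance must carry a confidence.  Matching is
    confidence-greedy per image, then all predictions are pooled and the
    confidence cutoff swept from high to low, emitting one point per
    distinct cutoff.  Confidence ties keep input order.
    """
    scored: list[tuple[float, bool]] = []  # (confidence, is_tp)
    n_gt = 0
    for gt, pred, conf in images:
        pids = instance_ids(pred)
        if conf is None:
            raise MissingConfidenceError("predictions carry no confidences")
        missing = [p for p in pids if p not in conf]
        if missing:
            raise MissingConfidenceError(
                f"prediction ids without confidence: {missing}"
            )
        n_gt += len(instance_ids(gt))
        m = match_by_confidence(gt, pred, conf, threshold, strict)
        tp_ids = {p for _, p, _ in m.pairs}
        for pid in pids:
            scored.append((float(conf[pid]), pid in tp_ids))
    if not scored:
        return PRCurve(points=(), cutoffs=())
    scored.sort(key=lambda t: -t[0])  # stable: input order on ties
    points: list[tuple[float, float]] = []
    cutoffs: list[float] = []
    tp = fp = 0
    for i, (conf_val, is_tp) in enumerate(scored):
        tp += int(is_tp)
        fp += int(not is_tp)
        last_at_cutoff = i + 1 == len(scored) or scored[i + 1][0] != conf_val
        if last_at_cutoff:
            rec = tp / n_gt if n_gt else 0.0
            prec = tp / (tp + fp)
            points.append((rec, prec))
            cutoffs.append(conf_val)
    return PRCurve(points=tuple(points), cutoffs=tuple(cutoffs))


def ap1(
    curve: PRCurve,
    interpolation: str = "all_points",
    envelope: bool = True,
) -> float:
    """Area under the precision-recall curve.

    ``all_points`` integrates the precision envelope exactly over recall in
    [0, 1] (PASCAL VOC 2010+ style); ``coco_101`` averages the envelope at
    101 evenly spaced recall values.  ``envelope=False`` integrates the raw
    precision instead — the integral notation in the literature does not
    force the monotone envelope, so both are available.  An empty curve
    (no predictions) scores 0.
    """
    if not curve.points:
        return 0.0
    recs = np.array([r for r, _ in curve.points])
    precs = np.array([p for _, p in curve.points])
    if envelope:
        precs = np.maximum.accumulate(precs[::-1])[::-1]
    if interpolation == "all_points":
        prev_r = 0.0
        area = 0.0
        for r, p in zip(recs, precs):
            area += (r - prev_r) * p
            prev_r = r
        return float(area)
    if interpolation == "coco_101":
        grid = np.linspace(0.0, 1.0, 101)
        # precision at recall >= g; 0 beyond the last achieved recall
        samples = np.zeros_like(grid)
        for i, g in enumerate(grid):
            mask = recs >= g - 1e-12
            if mask.any():
                samples[i] = precs[mask][0]
        return float(samples.mean())
    raise ValueError(f"unknown interpolation {interpolation!r}")


# ---------------------------------------------------------------------------
# Averaging combinators
# ---------------------------------------------------------------------------

def threshold_average(
    base: Callable[[float], float], thresholds: Iterable[float]
) -> float:
    """Mean of a base metric re-evaluated at each IoU threshold.

    This is the "mean" of the COCO metric (AP1 averaged over thresholds)
    and of the ranged threat-score and precision variants.
    """
    values = [base(float(t)) for t in thresholds]
    if not values:
        raise EmptyDatasetError("threshold range is empty")
    return float(np.mean(values))


def image_average(
    base: Callable[[object], float], per_image_inputs: Sequence
) -> float:
    """Mean of a base metric computed independently on each image.

    Every image gets the same weight regardless of how many objects it
    contains — the averaged-by-image reading of "mean", which can differ
    notably from pooling counts over the dataset first.
    """
    if not per_image_inputs:
        raise EmptyDatasetError("cannot average over an empty dataset")
    return float(np.mean([base(x) for x in per_image_inputs]))


def class_average(
    base: Callable[[object], float], per_class_inputs: Mapping
) -> float:
    """Mean of a base metric over classes (the original reading of mAP)."""
    if not per_class_inputs:
        raise EmptyDatasetError("cannot average over an empty class set")
    return float(np.mean([base(v) for v in per_class_inputs.values()]))
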