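"""Instance matching: the TP/FP/FN primitive every object-level metric consumes.

Given a ground-truth and a predicted label mask, a prediction counts as a
true positive when its intersection-over-union (IoU) with a ground-truth
instance exceeds a chosen threshold; each ground-truth instance can absorb
at most one prediction.  Unmatched ground-truth instances are false
negatives, unmatched predictions false positives.

The threshold comparison is strict (``IoU > t``) by default; pass
``strict=False`` for the ``>=`` convention some tools use.  For thresholds
at or above 0.5 the qualifying partner of any instance is unique (two
predictions cannot each overlap the same object by more than half of the
union), so the matching is forced; below 0.5 a maximum-total-IoU one-to-one
assignment is used.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.optimize import linear_sum_assignment

from .errors import ShapeMismatchError

__all__ = [
    "ConfusionCounts",
    "MatchResult",
    "pairwise_iou",
    "match_instances",
    "match_by_confidence",
    "confusion_counts",
    "pixel_confusion",
    "instance_ids",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Object (or pixel) counts of true/false positives and false negatives."""

    tp: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn)


@dataclass(frozen=True)
class MatchResult:
    """Outcome of matching one image pair at one IoU threshold.

    ``pairs`` holds the matched ``(gt_id, pred_id, iou)`` triples;
    ``unmatched_gt`` are the false negatives, ``unmatched_pred`` the false
    positives.
    """

    threshold: float
    pairs: tuple[tuple[int, int, float], ...]
    unmatched_gt: frozenset[int]
    unmatched_pred: frozenset[int]


def _check_shapes(gt: np.ndarray, pred: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    gt = np.asarray(gt)
    pred = np.asarray(pred)
    if gt.shape != pred.shape:
        raise ShapeMismatchError(
            f"mask shapes differ: gt {gt.shape} vs pred {pred.shape}"
        )
    return gt, pred


def instance_ids(mask: np.ndarray) -> list[int]:
    """Sorted positive instance ids present in a mask."""
    ids = np.unique(np.asarray(mask))
    return [int(i) for i in ids if i > 0]


def pairwise_iou(
    gt: np.ndarray, pred: np.ndarray
) -> dict[tuple[int, int], float]:
    """IoU for every (gt instance, pred instance) pair that overlaps.

    Pairs with empty intersection are absent.  Areas and intersections are
    exact pixel counts; each IoU is a single integer division, so there is
    no accumulation error.
    """
    gt, pred = _check_shapes(gt, pred)
    g = gt.ravel()
    p = pred.ravel()
    both = (g > 0) & (p > 0)
    if not both.any():
        return {}
    gt_ids, gt_areas = np.unique(g[g > 0], return_counts=True)
    pred_ids, pred_areas = np.unique(p[p > 0], return_counts=True)
    area_g = dict(zip(gt_ids.tolist(), gt_areas.tolist()))
    area_p = dict(zip(pred_ids.tolist(), pred_areas.tolist()))
    pairs, inter = np.unique(
        np.stack([g[both], p[both]]), axis=1, return_counts=True
    )
    out: dict[tuple[int, int], float] = {}
    for (gi, pi), n in zip(pairs.T.tolist(), inter.tolist()):
        out[(int(gi), int(pi))] = n / (area_g[gi] + area_p[pi] - n)
    return out


def _qualifies(iou: float, threshold: float, strict: bool) -> bool:
    return iou > threshold if strict else iou >= threshold


def match_instances(
    gt: np.ndarray,
    pred: np.ndarray,
    threshold: float,
    strict: bool = True,
) -> MatchResult:
    """One-to-one matching of predictions to ground truth at an IoU threshold.

    Among pairs whose IoU qualifies (``> threshold``, or ``>=`` with
    ``strict=False``), the assignment maximises total matched IoU; at
    thresholds >= 0.5 that assignment is the unique qualifying pairing.
    Ties are resolved deterministically (ids processed in sorted order).
    """
    if not 0.0 <= threshold < 1.0:
        raise ValueError(f"threshold must be in [0, 1), got {threshold}")
    ious = pairwise_iou(gt, pred)
    qual = {k: v for k, v in ious.items()
            if _qualifies(v, threshold, strict)}
    pairs: list[tuple[int, int, float]] = []
    if qual:
        gs = sorted({k[0] for k in qual})
        ps = sorted({k[1] for k in qual})
        g_index = {g: i for i, g in enumerate(gs)}
        p_index = {p: j for j, p in enumerate(ps)}
        weights = np.zeros((len(gs), len(ps)))
        for (gi, pi), v in qual.items():
            weights[g_index[gi], p_index[pi]] = v
        rows, cols = linear_sum_assignment(weights, maximize=True)
        for r, c in zip(rows, cols):
            if (gs[r], ps[c]) in qual:
                pairs.append((gs[r], ps[c], qual[(gs[r], ps[c])]))
        pairs.sort(key=lambda t: (t[0], t[1]))
    matched_g = {g for g, _, _ in pairs}
    matched_p = {p for _, p, _ in pairs}
    return MatchResult(
        threshold=threshold,
        pairs=tuple(pairs),
        unmatched_gt=frozenset(g for g in instance_ids(gt) if g not in matched_g),
        unmatched_pred=frozenset(p for p in instance_ids(pred) if p not in matched_p),
    )


def match_by_confidence(
    gt: np.ndarray,
    pred: np.ndarray,
    confidences: Mapping[int, float],
    threshold: float,
    strict: bool = True,
) -> MatchResult:
    """Greedy matching that gives higher-confidence predictions priority.

    Predictions are processed in descending confidence (input order on
    ties); each takes the still-unmatched ground-truth instance with the
    highest qualifying IoU.  This is the matching under which a
    precision-recall curve is consistent: a prediction's TP/FP status never
    depends on lower-ranked predictions.
    """
    if not 0.0 <= threshold < 1.0:
        raise ValueError(f"threshold must be in [0, 1), got {threshold}")
    gt, pred = _check_shapes(gt, pred)
    ious = pairwise_iou(gt, pred)
    by_pred: dict[int, list[tuple[int, float]]] = {}
    for (gi, pi), v in ious.items():
        if _qualifies(v, threshold, strict):
            by_pred.setdefault(pi, []).append((gi, v))
    order = sorted(
        enumerate(confidences.items()), key=lambda t: (-t[1][1], t[0])
    )
    taken: set[int] = set()
    pairs: list[tuple[int, int, float]] = []
    for _, (pid, _conf) in order:
        candidates = [(gi, v) for gi, v in by_pred.get(pid, ())
                      if gi not in taken]
        if candidates:
            gi, v = max(candidates, key=lambda t: (t[1], -t[0]))
            taken.add(gi)
            pairs.append((gi, pid, v))
    pairs.sort(key=lambda t: (t[0], t[1]))
    matched_p = {p for _, p, _ in pairs}
    return MatchResult(
        threshold=threshold,
        pairs=tuple(pairs),
        unmatched_gt=frozenset(g for g in instance_ids(gt) if g not in taken),
        unmatched_pred=frozenset(p for p in instance_ids(pred)
                                 if p not in matched_p),
    )


def confusion_counts(m: MatchResult) -> ConfusionCounts:
    """TP/FP/FN counts of a match result."""
    return ConfusionCounts(tp=len(m.pairs), fp=len(m.unmatched_pred),
                           fn=len(m.unmatched_gt))


def pixel_confusion(gt: np.ndarray, pred: np.ndarray) -> ConfusionCounts:
    """Foreground-vs-background pixel counts (the pixel-level metric atom)."""
    gt, pred = _check_shapes(gt, pred)
    g = gt > 0
    p = pred > 0
    return ConfusionCounts(
        tp=int(np.count_nonzero(g & p)),
        fp=int(np.count_nonzero(~g & p)),
        fn=int(np.count_nonzero(g & ~p)),
    )
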