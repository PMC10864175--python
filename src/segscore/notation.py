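"""Unambiguous metric notation: parsing, formatting, and dispatch.

A metric name alone ("AP", "mAP") does not identify a computation: at least
six incompatible readings coexist in the segmentation literature, differing
in whether counts are pooled over the dataset or averaged per image, which
IoU threshold(s) apply, and whether classes are averaged.  This module
implements a notation that pins every axis down::

    <base>_<agg|avg>^<threshold>
    <base>_<agg|avg>^<start>:<step>:<stop>
    px:<base>_<agg|avg>^<threshold>          (pixel-level simple metrics)

for example ``TS_agg^0.5:0.05:0.95`` (threat score, counts pooled over the
dataset, averaged over IoU thresholds 0.5, 0.55, ..., 0.95) or
``F1_avg^0.5`` (F1 at IoU 0.5, computed per image and averaged).

``base`` is one of the simple metrics (``TS``, ``F1``, ``precision``,
``recall``), ``PQ``, or an explicitly numbered historical variant
``AP1``..``AP4`` / ``mAP1``..``mAP6``.  The bare tokens ``AP`` and ``mAP``
are rejected on purpose: if the classical definition is meant, ask for
``AP1``/``mAP1``; if the threat score is meant, say so.  ``@IoU=`` is
accepted as an input alias for ``^``.

:func:`evaluate_spec` routes a parsed spec to the metrics engine.  The
numbered variants expand as catalogued:

====== ===========================================================
AP1    area under the confidence-swept precision-recall curve
mAP1   class mean of AP1
AP2    threat score TP/(TP+FP+FN) at a fixed threshold
mAP2   mean of aggregated AP2 over an IoU threshold range
AP3    mean of aggregated precision over a threshold range
mAP3   image mean of AP3
mAP4   precision x recall ("Digits score")
mAP5   image mean of per-image mAP2
AP4    mean of AP1 over a threshold range (the "COCO metric")
mAP6   class mean of AP4 (the primary COCO competition metric)
====== ===========================================================
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import metrics as M
from .dataset import ImagePair, class_labels, restrict_to_class
from .errors import EmptyDatasetError, SpecParseError
from .matching import (
    ConfusionCounts,
    confusion_counts,
    match_instances,
    pixel_confusion,
)

__all__ = [
    "ThresholdRange",
    "MetricSpec",
    "parse_spec",
    "format_spec",
    "evaluate_spec",
    "BASE_METRICS",
]

BASE_METRICS = (
    "TS", "F1", "precision", "recall", "PQ",
    "AP1", "AP2", "AP3", "AP4",
    "mAP1", "mAP2", "mAP3", "mAP4", "mAP5", "mAP6",
)

_SIMPLE_BASES = {"TS": "threat_score", "F1": "f1",
                 "precision": "precision", "recall": "recall",
                 "AP2": "threat_score"}
_PIXEL_BASES = {"TS", "F1", "precision", "recall"}
_CONFIDENCE_BASES = {"AP1", "AP4", "mAP1", "mAP6"}


@dataclass(frozen=True)
class ThresholdRange:
    """An inclusive IoU threshold grid ``start, start+step, ..., <= stop``.

    A single threshold is the degenerate range ``start == stop`` (step
    unused).  Values are rounded onto the step grid so that e.g.
    0.5 + 9 x 0.05 is exactly 0.95.
    """

    start: float
    stop: float
    step: float | None = None

    def __post_init__(self):
        if not (0.0 <= self.start < 1.0 and 0.0 <= self.stop < 1.0):
            raise ValueError(f"thresholds must lie in [0, 1): {self}")
        if self.stop < self.start:
            raise ValueError(f"stop < start in threshold range: {self}")
        if self.stop > self.start and (self.step is None or self.step <= 0):
            raise ValueError(f"a multi-value range needs step > 0: {self}")

    @classmethod
    def single(cls, t: float) -> "ThresholdRange":
        return cls(start=t, stop=t)

    @property
    def values(self) -> tuple[float, ...]:
        if self.stop == self.start:
            return (self.start,)
        n = int(np.floor((self.stop - self.start) / self.step + 1e-9))
        return tuple(round(self.start + k * self.step, 10)
                     for k in range(n + 1))

    @property
    def is_single(self) -> bool:
        return self.stop == self.start


@dataclass(frozen=True)
class MetricSpec:
    """A fully disambiguated metric identity."""

    base: str
    mode: str  # "agg" | "avg"
    thresholds: ThresholdRange
    level: str = "object"  # "object" | "pixel"
    strict_iou: bool = True

    def __post_init__(self):
        if self.base not in BASE_METRICS:
            raise SpecParseError(
                f"unknown base metric {self.base!r}; valid: "
                + ", ".join(BASE_METRICS)
            )
        if self.mode not in ("agg", "avg"):
            raise SpecParseError(f"mode must be 'agg' or 'avg', got {self.mode!r}")
        if self.level not in ("object", "pixel"):
            raise SpecParseError(f"level must be 'object' or 'pixel'")
        if self.level == "pixel" and self.base not in _PIXEL_BASES:
            raise SpecParseError(
                f"pixel-level scores exist only for the simple metrics "
                f"({', '.join(sorted(_PIXEL_BASES))}), not {self.base!r}"
            )

    def __str__(self) -> str:
        return format_spec(self)


def _fmt_num(x: float) -> str:
    return format(x, "g")


def format_spec(spec: MetricSpec) -> str:
    """Canonical string form; round trips with :func:`parse_spec`."""
    tr = spec.thresholds
    if tr.is_single:
        thr = _fmt_num(tr.start)
    else:
        thr = f"{_fmt_num(tr.start)}:{_fmt_num(tr.step)}:{_fmt_num(tr.stop)}"
    prefix = "px:" if spec.level == "pixel" else ""
    return f"{prefix}{spec.base}_{spec.mode}^{thr}"


_ALIAS_RE = re.compile(r"@\(?IoU=([^)]*)\)?$")


def parse_spec(s: str) -> MetricSpec:
    """Parse a metric-notation string (whitespace-insensitive).

    Raises :class:`SpecParseError` for unknown bases, the deliberately
    rejected bare ``AP``/``mAP`` tokens, and malformed threshold ranges.
    """
    text = re.sub(r"\s+", "", s)
    level = "object"
    if text.startswith("px:"):
        level = "pixel"
        text = text[3:]
    alias = _ALIAS_RE.search(text)
    if alias:
        head, thr_text = text[: alias.start()], alias.group(1)
    elif "^" in text:
        head, _, thr_text = text.partition("^")
    else:
        raise SpecParseError(
            f"{s!r}: no threshold part; IoU thresholds must be denoted "
            f"explicitly, e.g. TS_agg^0.5 or TS_agg^0.5:0.05:0.95"
        )
    base, sep, mode = head.rpartition("_")
    if not sep:
        raise SpecParseError(
            f"{s!r}: missing aggregation mode; whether a metric is "
            f"aggregated (_agg) or averaged over images (_avg) must be "
            f"explicit"
        )
    if base in ("AP", "mAP"):
        raise SpecParseError(
            f"{base!r} is ambiguous and rejected: at least six incompatible "
            f"readings coexist. Use 'TS' if the threat score is meant, or an "
            f"explicitly numbered variant (AP1..AP4, mAP1..mAP6)."
        )
    if base not in BASE_METRICS:
        raise SpecParseError(
            f"unknown base metric {base!r}; valid: " + ", ".join(BASE_METRICS)
        )
    parts = thr_text.split(":")
    try:
        if len(parts) == 1:
            tr = ThresholdRange.single(float(parts[0]))
        elif len(parts) == 3:
            tr = ThresholdRange(start=float(parts[0]), step=float(parts[1]),
                                stop=float(parts[2]))
        else:
            raise ValueError("expected t or start:step:stop")
    except ValueError as exc:
        raise SpecParseError(f"{s!r}: malformed threshold range: {exc}") from exc
    return MetricSpec(base=base, mode=mode, thresholds=tr, level=level)


# ---------------------------------------------------------------------------
# Dispatch
# ---------------------------------------------------------------------------

def evaluate_spec(
    spec: MetricSpec | str,
    dataset: Sequence[ImagePair],
    empty_score: float = 1.0,
) -> float:
    """Evaluate a fully specified metric on a per-image dataset.

    ``agg`` pools TP/FP/FN (and matched IoUs, and PR points) over all
    images before applying the base formula; ``avg`` computes the score per
    image and averages.  Ranged thresholds re-run the matching at each
    threshold value and average the resulting scores.
    """
    if isinstance(spec, str):
        spec = parse_spec(spec)
    if not dataset:
        raise EmptyDatasetError("dataset is empty")

    if spec.level == "pixel":
        return _evaluate_pixel(spec, dataset, empty_score)
    return _evaluate_object(spec, dataset, empty_score)


def _evaluate_pixel(spec, dataset, empty_score):
    name = _SIMPLE_BASES[spec.base]
    fn = getattr(M, {"threat_score": "threat_score", "f1": "f1_score",
                     "precision": "precision", "recall": "recall"}[name])
    counts = [pixel_confusion(p.gt, p.pred) for p in dataset]
    if spec.mode == "agg":
        total = ConfusionCounts(0, 0, 0)
        for c in counts:
            total = total + c
        return fn(total, empty_score)
    return M.image_average(lambda c: fn(c, empty_score), counts)


def _evaluate_object(spec, dataset, empty_score):
    strict = spec.strict_iou
    thr = spec.thresholds.values

    def counts_at(pair: ImagePair, t: float) -> ConfusionCounts:
        return confusion_counts(match_instances(pair.gt, pair.pred, t, strict))

    def pooled(t: float) -> ConfusionCounts:
        total = ConfusionCounts(0, 0, 0)
        for pair in dataset:
            total = total + counts_at(pair, t)
        return total

    def simple_score(name: str, t: float, images=None) -> float:
        images = dataset if images is None else images
        fn = {"threat_score": M.threat_score, "f1": M.f1_score,
              "precision": M.precision, "recall": M.recall,
              "digits": M.digits_score}[name]
        if spec.mode == "agg" or images is not dataset:
            total = ConfusionCounts(0, 0, 0)
            for pair in images:
                total = total + counts_at(pair, t)
            return fn(total, empty_score)
        return M.image_average(
            lambda pair: fn(counts_at(pair, t), empty_score), list(images)
        )

    def pq_at(t: float) -> float:
        if spec.mode == "agg":
            # pool matched IoUs and counts over the dataset, then the formula
            iou_sum = 0.0
            tp = fp = fn_ = 0
            for pair in dataset:
                m = match_instances(pair.gt, pair.pred, t, strict)
                iou_sum += sum(i for _, _, i in m.pairs)
                tp += len(m.pairs)
                fp += len(m.unmatched_pred)
                fn_ += len(m.unmatched_gt)
            denom = tp + (fp + fn_) / 2.0
            return iou_sum / denom if denom else 0.0
        return M.image_average(
            lambda pair: M.panoptic_quality(
                match_instances(pair.gt, pair.pred, t, strict)
            ),
            list(dataset),
        )

    def ap1_at(t: float, images=None) -> float:
        images = dataset if images is None else images
        triples = [(p.gt, p.pred, p.confidences) for p in images]
        return M.ap1(M.build_pr_curve(triples, t, strict))

    def ap1_mode(t: float) -> float:
        if spec.mode == "agg":
            return ap1_at(t)
        return M.image_average(lambda pair: ap1_at(t, [pair]), list(dataset))

    base = spec.base
    if base in _SIMPLE_BASES:
        name = _SIMPLE_BASES[base]
        return M.threshold_average(lambda t: simple_score(name, t), thr)
    if base == "mAP4":
        return M.threshold_average(lambda t: simple_score("digits", t), thr)
    if base == "PQ":
        return M.threshold_average(pq_at, thr)
    if base == "AP1":
        return M.threshold_average(ap1_mode, thr)
    if base == "AP4":
        # definitionally a threshold mean of AP1; identical routing to a
        # ranged AP1, kept as a distinct name for the comparison study
        return M.threshold_average(ap1_mode, thr)
    if base == "AP3":
        if spec.mode == "agg":
            return M.threshold_average(
                lambda t: simple_score("precision", t, dataset), thr
            )
        return M.image_average(
            lambda pair: M.threshold_average(
                lambda t: simple_score("precision", t, [pair]), thr
            ),
            list(dataset),
        )
    if base == "mAP2":
        if spec.mode == "agg":
            return M.threshold_average(
                lambda t: simple_score("threat_score", t, dataset), thr
            )
        return _map5(dataset, thr, strict, empty_score)
    if base == "mAP3":
        return M.image_average(
            lambda pair: M.threshold_average(
                lambda t: simple_score("precision", t, [pair]), thr
            ),
            list(dataset),
        )
    if base == "mAP5":
        return _map5(dataset, thr, strict, empty_score)
    if base in ("mAP1", "mAP6"):
        labels = class_labels(dataset)

        def per_class(label: str) -> float:
            sub = [restrict_to_class(p, label) for p in dataset]
            return M.threshold_average(lambda t: ap1_at(t, sub), thr)

        return M.class_average(per_class, {lb: lb for lb in labels})
    raise SpecParseError(f"unhandled base {base!r}")  # pragma: no cover


def _map5(dataset, thr, strict, empty_score):
    """Image mean of per-image threshold-averaged threat score."""
    def per_image(pair: ImagePair) -> float:
        def ts_at(t: float) -> float:
            c = confusion_counts(match_instances(pair.gt, pair.pred, t, strict))
            return M.threat_score(c, empty_score)
        return M.threshold_average(ts_at, thr)
    return M.image_average(per_image, list(dataset))
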