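"""The per-image dataset container that dataset-level evaluation consumes."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np


@dataclass
class ImagePair:
    """One image's ground truth and prediction, plus optional annotations.

    ``confidences`` maps predicted instance id -> confidence in [0, 1]
    (required only by curve-based metrics).  ``gt_classes`` /
    ``pred_classes`` map instance id -> class label; instances without an
    entry belong to the implicit single class.
    """

    gt: np.ndarray
    pred: np.ndarray
    confidences: Mapping[int, float] | None = None
    gt_classes: Mapping[int, str] | None = None
    pred_classes: Mapping[int, str] | None = None
    image_id: str | None = None


def restrict_to_class(pair: ImagePair, label: str) -> ImagePair:
    """Zero out instances not belonging to ``label`` in both masks.

    Instances with no class annotation are kept only for the implicit
    default class (``"__default__"``).
    """
    def _filter(mask: np.ndarray, classes: Mapping[int, str] | None) -> np.ndarray:
        if classes is None:
            return mask if label == DEFAULT_CLASS else np.zeros_like(mask)
        out = np.array(mask, copy=True)
        for inst in np.unique(mask):
            if inst > 0 and classes.get(int(inst), DEFAULT_CLASS) != label:
                out[out == inst] = 0
        return out

    return ImagePair(
        gt=_filter(pair.gt, pair.gt_classes),
        pred=_filter(pair.pred, pair.pred_classes),
        confidences=pair.confidences,
        image_id=pair.image_id,
    )


DEFAULT_CLASS = "__default__"


def class_labels(dataset) -> list[str]:
    """All class labels present in a dataset (sorted); the implicit default
    class if no instance is annotated."""
    labels: set[str] = set()
    for pair in dataset:
        for classes, mask in ((pair.gt_classes, pair.gt),
                              (pair.pred_classes, pair.pred)):
            ids = {int(i) for i in np.unique(mask) if i > 0}
            if classes is None:
                if ids:
                    labels.add(DEFAULT_CLASS)
            else:
                labels.update(classes.get(i, DEFAULT_CLASS) for i in ids)
    return sorted(labels) if labels else [DEFAULT_CLASS]
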