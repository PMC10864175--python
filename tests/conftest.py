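"""Shared fixtures and random-scene builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20230727)


def grid_gt(rng, shape=(48, 48), n_objects=6, cell=8, obj_size=(3, 6)):
    """Ground truth of up to ``n_objects`` disjoint rectangles, one per grid
    cell, so instances never touch and IoUs are easy to reason about."""
    h, w = shape
    cells = [(r, c) for r in range(h // cell) for c in range(w // cell)]
    rng.shuffle(cells)
    mask = np.zeros(shape, dtype=np.int32)
    for i, (cr, cc) in enumerate(cells[:n_objects], start=1):
        oh = int(rng.integers(obj_size[0], obj_size[1] + 1))
        ow = int(rng.integers(obj_size[0], obj_size[1] + 1))
        r0 = cr * cell + int(rng.integers(0, cell - oh))
        c0 = cc * cell + int(rng.integers(0, cell - ow))
        mask[r0:r0 + oh, c0:c0 + ow] = i
    return mask


def jitter_pred(rng, gt, max_shift=1, drop_p=0.15, n_extra=1, shape_extra=(3, 5)):
    """Prediction derived from gt: instances shifted by up to ``max_shift``
    pixels (drawn onto free pixels only), some dropped, plus spurious boxes.
    Prediction ids are re-labelled with an offset so id sets differ from gt."""
    h, w = gt.shape
    pred = np.zeros_like(gt)
    next_id = 101
    for gid in sorted(int(i) for i in np.unique(gt) if i > 0):
        if rng.random() < drop_p:
            continue
        rr, cc = np.nonzero(gt == gid)
        dr = int(rng.integers(-max_shift, max_shift + 1))
        dc = int(rng.integers(-max_shift, max_shift + 1))
        rr, cc = rr + dr, cc + dc
        keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        rr, cc = rr[keep], cc[keep]
        free = pred[rr, cc] == 0
        if free.any():
            pred[rr[free], cc[free]] = next_id
            next_id += 1
    for _ in range(int(rng.integers(0, n_extra + 1))):
        oh = int(rng.integers(*shape_extra))
        ow = int(rng.integers(*shape_extra))
        r0 = int(rng.integers(0, h - oh))
        c0 = int(rng.integers(0, w - ow))
        region = pred[r0:r0 + oh, c0:c0 + ow]
        if (region == 0).all():
            pred[r0:r0 + oh, c0:c0 + ow] = next_id
            next_id += 1
    return pred


def random_confidences(rng, pred):
    """Random confidences in (0, 1) for every predicted instance."""
    return {int(i): float(rng.uniform(0.05, 1.0))
            for i in np.unique(pred) if i > 0}
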