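"""Synthetic instance-segmentation benchmarks with controllable degradation.

The generator emulates the structure of multi-image segmentation-challenge
datasets — many non-overlapping blob-like objects per image — without any
microscopy content: ground truth is a set of random ellipses or rectangles
placed with a minimum gap, and "submissions" are the ground truth degraded
through three independent channels that map one-to-one onto the error types
the object-level metrics count:

* **drops** (probability ``drop_rate`` per object) produce false negatives;
* **spurious objects** (Poisson with mean ``spurious_rate`` per image)
  produce false positives;
* **jitter** (integer pixel shifts up to ``shift_px`` plus random
  dilation/erosion up to ``morph_px``) degrades the IoU of survivors, so
  threshold sweeps and PQ become informative.

Each surviving prediction also carries a confidence — its true IoU against
the ground truth plus clipped Gaussian noise — so confidence-swept
precision-recall metrics (AP1 and friends) are exercisable.

Everything is reproducible: one seed per cohort, with per-image and
per-submission substreams derived through ``numpy.random.SeedSequence`` so
adding an image or a submission never perturbs earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from skimage.draw import ellipse as _draw_ellipse
from skimage.morphology import dilation as _dilate, disk, erosion as _erode

from .errors import CapacityError, ValidationError
from .instance_io import write_mask_image, write_rle_csv

__all__ = [
    "SceneConfig",
    "DegradeConfig",
    "generate_scene",
    "degrade",
    "quality_ladder",
    "generate_cohort",
    "write_cohort",
]


@dataclass(frozen=True)
class SceneConfig:
    """Ground-truth scene parameters.

    ``n_objects`` is either a fixed count or an inclusive ``(lo, hi)``
    sampling range; ``size_range`` is the object diameter range in pixels;
    ``min_gap`` the minimum background gap between instances.
    """

    image_size: tuple[int, int] = (256, 256)
    n_objects: int | tuple[int, int] = 15
    object_shape: str = "ellipse"  # "ellipse" | "rectangle"
    size_range: tuple[int, int] = (10, 24)
    min_gap: int = 2
    seed: int | np.random.SeedSequence = 0

    def __post_init__(self):
        if self.object_shape not in ("ellipse", "rectangle"):
            raise ValidationError(
                f"object_shape must be 'ellipse' or 'rectangle', "
                f"got {self.object_shape!r}"
            )
        lo, hi = self.size_range
        if not (2 <= lo <= hi):
            raise ValidationError(f"size_range invalid: {self.size_range}")
        if self.min_gap < 0:
            raise ValidationError("min_gap must be >= 0")


@dataclass(frozen=True)
class DegradeConfig:
    """Degradation parameters, one error channel per metric error type.

    ``drop_rate`` in [0,1]; ``spurious_rate`` >= 0 (expected extra objects
    per image); ``shift_px``/``morph_px`` nonnegative integer jitter
    scales; ``confidence_noise`` is the s.d. of Gaussian noise added to the
    true IoU before clipping to [0,1].
    """

    drop_rate: float = 0.0
    spurious_rate: float = 0.0
    shift_px: int = 0
    morph_px: int = 0
    confidence_noise: float = 0.1
    seed: int | np.random.SeedSequence = 0

    def __post_init__(self):
        if not 0.0 <= self.drop_rate <= 1.0:
            raise ValidationError(f"drop_rate must be in [0,1], got {self.drop_rate}")
        if self.spurious_rate < 0:
            raise ValidationError("spurious_rate must be >= 0")
        if self.shift_px < 0 or self.morph_px < 0:
            raise ValidationError("jitter scales must be >= 0")
        if self.confidence_noise < 0:
            raise ValidationError("confidence_noise must be >= 0")


def _object_pixels(rng, shape, size_range, h, w):
    """Sample one object's pixel coordinates, fully inside the image."""
    lo, hi = size_range
    ra = rng.uniform(lo / 2, hi / 2)
    rb = rng.uniform(lo / 2, hi / 2)
    pad_r, pad_c = int(np.ceil(ra)) + 1, int(np.ceil(rb)) + 1
    if 2 * pad_r >= h or 2 * pad_c >= w:
        return None
    r0 = int(rng.integers(pad_r, h - pad_r))
    c0 = int(rng.integers(pad_c, w - pad_c))
    if shape == "ellipse":
        rr, cc = _draw_ellipse(r0, c0, ra, rb, shape=(h, w))
    else:
        hr, hc = max(1, int(ra)), max(1, int(rb))
        rr, cc = np.meshgrid(np.arange(r0 - hr, r0 + hr + 1),
                             np.arange(c0 - hc, c0 + hc + 1), indexing="ij")
        rr, cc = rr.ravel(), cc.ravel()
    return rr, cc


def generate_scene(cfg: SceneConfig) -> np.ndarray:
    """Generate one ground-truth label mask.

    Objects are placed by rejection sampling against a forbidden mask (the
    existing foreground dilated by ``min_gap``); if an object cannot be
    placed within the retry budget a :class:`CapacityError` reports how
    many did fit.  Identical configs (and seeds) give identical masks.
    """
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.image_size
    if isinstance(cfg.n_objects, tuple):
        lo, hi = cfg.n_objects
        n = int(rng.integers(lo, hi + 1))
    else:
        n = int(cfg.n_objects)
    labels = np.zeros((h, w), dtype=np.int32)
    forbidden = np.zeros((h, w), dtype=bool)
    footprint = disk(cfg.min_gap) if cfg.min_gap > 0 else None
    max_tries = 200
    for k in range(1, n + 1):
        for _ in range(max_tries):
            sampled = _object_pixels(rng, cfg.object_shape, cfg.size_range, h, w)
            if sampled is None:
                break
            rr, cc = sampled
            if forbidden[rr, cc].any():
                continue
            labels[rr, cc] = k
            obj = np.zeros((h, w), dtype=bool)
            obj[rr, cc] = True
            forbidden |= _dilate(obj, footprint) if footprint is not None else obj
            break
        else:
            raise CapacityError(requested=n, achieved=k - 1)
        if sampled is None:
            raise CapacityError(requested=n, achieved=k - 1)
    return labels


def _shift(mask: np.ndarray, dr: int, dc: int) -> np.ndarray:
    """Shift a boolean mask by whole pixels, clipping at the borders."""
    h, w = mask.shape
    out = np.zeros_like(mask)
    src_r = slice(max(0, -dr), min(h, h - dr))
    dst_r = slice(max(0, dr), min(h, h + dr))
    src_c = slice(max(0, -dc), min(w, w - dc))
    dst_c = slice(max(0, dc), min(w, w + dc))
    out[dst_r, dst_c] = mask[src_r, src_c]
    return out


def degrade(
    gt: np.ndarray, cfg: DegradeConfig
) -> tuple[np.ndarray, dict[int, float]]:
    """Degrade a ground-truth mask into a prediction with confidences.

    Surviving objects are shifted and dilated/eroded independently, then
    drawn in id order onto free pixels only (predictions stay
    non-overlapping); spurious ellipses are added to the remaining
    background.  Each predicted id gets confidence = clip(true IoU +
    N(0, confidence_noise), 0, 1).
    """
    from .matching import pairwise_iou

    rng = np.random.default_rng(cfg.seed)
    gt = np.asarray(gt)
    h, w = gt.shape
    pred = np.zeros_like(gt, dtype=np.int32)
    next_id = 1
    for gid in sorted(int(i) for i in np.unique(gt) if i > 0):
        if rng.random() < cfg.drop_rate:
            continue
        obj = gt == gid
        if cfg.shift_px:
            dr, dc = rng.integers(-cfg.shift_px, cfg.shift_px + 1, size=2)
            obj = _shift(obj, int(dr), int(dc))
        if cfg.morph_px:
            radius = int(rng.integers(0, cfg.morph_px + 1))
            if radius:
                op = _dilate if rng.random() < 0.5 else _erode
                obj = op(obj, disk(radius))
        target = obj & (pred == 0)
        if target.any():
            pred[target] = next_id
            next_id += 1
    n_spurious = int(rng.poisson(cfg.spurious_rate))
    for _ in range(n_spurious):
        for _ in range(50):
            sampled = _object_pixels(rng, "ellipse", (6, 14), h, w)
            if sampled is None:
                break
            rr, cc = sampled
            if (pred[rr, cc] == 0).all():
                pred[rr, cc] = next_id
                next_id += 1
                break
    ious = pairwise_iou(gt, pred)
    best: dict[int, float] = {}
    for (_, pid), v in ious.items():
        best[pid] = max(best.get(pid, 0.0), v)
    confidences = {}
    for pid in sorted(int(i) for i in np.unique(pred) if i > 0):
        noise = rng.normal(0.0, cfg.confidence_noise) if cfg.confidence_noise else 0.0
        confidences[pid] = float(np.clip(best.get(pid, 0.0) + noise, 0.0, 1.0))
    return pred, confidences


def quality_ladder(
    n_submissions: int,
    max_drop: float = 0.5,
    max_shift: int = 3,
    max_morph: int = 1,
    spurious_rate: float = 0.0,
    confidence_noise: float = 0.1,
) -> list[DegradeConfig]:
    """A monotone ladder of degradation configs, best (index 0) to worst.

    Severity increases linearly: submission i of n gets drop rate
    ``i/(n-1) * max_drop`` and proportional jitter.
    """
    if n_submissions < 1:
        raise ValidationError("need at least one submission")
    ladder = []
    for i in range(n_submissions):
        frac = i / (n_submissions - 1) if n_submissions > 1 else 0.0
        ladder.append(DegradeConfig(
            drop_rate=frac * max_drop,
            spurious_rate=frac * spurious_rate,
            shift_px=int(round(frac * max_shift)),
            morph_px=int(round(frac * max_morph)),
            confidence_noise=confidence_noise,
        ))
    return ladder


def generate_cohort(
    n_images: int,
    ladder: Sequence[DegradeConfig],
    scene_cfg: SceneConfig | None = None,
    seed: int = 0,
    nested: bool = False,
) -> tuple[dict[str, np.ndarray], dict[str, dict[str, tuple[np.ndarray, dict[int, float]]]]]:
    """Generate a ground-truth dataset plus one submission per ladder rung.

    Returns ``(gt, submissions)`` where ``gt`` maps image id -> label mask
    and ``submissions`` maps submission id -> {image id -> (pred mask,
    confidences)}.  Substreams are derived per image and per
    (submission, image), so cohorts are byte-identical across runs and
    stable under extension.

    With ``nested=True`` the jitter/spurious channels are switched off and
    each submission's dropped-object set is a superset of every better
    submission's (drops follow one fixed per-image order), so every
    fixed-threshold metric ranks the submissions identically — a useful
    control cohort for rank-correlation experiments.
    """
    scene_cfg = scene_cfg or SceneConfig()
    gt: dict[str, np.ndarray] = {}
    image_ids = [f"img{i:03d}" for i in range(n_images)]
    for i, iid in enumerate(image_ids):
        ss = np.random.SeedSequence(entropy=(seed, 0, i))
        gt[iid] = generate_scene(replace(scene_cfg, seed=ss))
    submissions: dict[str, dict[str, tuple[np.ndarray, dict[int, float]]]] = {}
    if nested:
        drop_order = {}
        for i, iid in enumerate(image_ids):
            rng = np.random.default_rng(np.random.SeedSequence(entropy=(seed, 1, i)))
            ids = np.array(sorted(int(v) for v in np.unique(gt[iid]) if v > 0))
            drop_order[iid] = rng.permutation(ids)
        for s, cfg in enumerate(ladder):
            sub = {}
            for iid in image_ids:
                order = drop_order[iid]
                k = int(round(cfg.drop_rate * len(order)))
                dropped = set(int(v) for v in order[:k])
                mask = gt[iid]
                pred = np.zeros_like(mask, dtype=np.int32)
                conf = {}
                nid = 1
                for gid in sorted(int(v) for v in np.unique(mask) if v > 0):
                    if gid in dropped:
                        continue
                    pred[mask == gid] = nid
                    conf[nid] = 1.0
                    nid += 1
                sub[iid] = (pred, conf)
            submissions[f"sub{s:02d}"] = sub
    else:
        for s, cfg in enumerate(ladder):
            sub = {}
            for i, iid in enumerate(image_ids):
                ss = np.random.SeedSequence(entropy=(seed, 2, s, i))
                pred, conf = degrade(gt[iid], replace(cfg, seed=ss))
                sub[iid] = (pred, conf)
            submissions[f"sub{s:02d}"] = sub
    return gt, submissions


def write_cohort(
    outdir: str | Path,
    gt: Mapping[str, np.ndarray],
    submissions: Mapping[str, Mapping[str, tuple[np.ndarray, Mapping[int, float]]]],
) -> None:
    """Write a cohort as TIFF ground truth plus per-submission RLE CSV,
    mask TIFFs and a confidences JSON — exercising every I/O path."""
    import json

    outdir = Path(outdir)
    (outdir / "gt").mkdir(parents=True, exist_ok=True)
    for iid, mask in gt.items():
        write_mask_image(mask, outdir / "gt" / f"{iid}.tif")
    for sid, sub in submissions.items():
        subdir = outdir / "submissions" / sid
        subdir.mkdir(parents=True, exist_ok=True)
        masks = {iid: pred for iid, (pred, _) in sub.items()}
        for iid, pred in masks.items():
            write_mask_image(pred, subdir / f"{iid}.tif")
        write_rle_csv(subdir / "submission.csv", masks)
        conf_doc = {iid: {str(k): v for k, v in conf.items()}
                    for iid, (_, conf) in sub.items()}
        with open(subdir / "confidences.json", "w") as fh:
            json.dump(conf_doc, fh, indent=1)
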