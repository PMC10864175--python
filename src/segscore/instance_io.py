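"""Reading, writing and converting instance representations.

Three on-disk representations used by the nuclei/cell segmentation and
mitosis detection communities are supported:

* **Label images** — 2-D single-channel integer TIFF or PNG where 0 is
  background and each positive value is one instance.
* **Kaggle run-length encoding (RLE)** — the submission dialect of the 2018
  Data Science Bowl and 2021 Sartorius challenges: 1-based pixel indices in
  column-major order (down the first column, then the second, ...), encoded
  as space-separated ``start length`` pairs, one instance per CSV row with
  columns ``ImageId`` and ``EncodedPixels``.
* **Detection JSON** — centroid lists for detection tasks (mitotic figures),
  optionally with confidences and class labels.  The schema is this
  package's own (see :func:`read_detections`).

Internally a label mask is simply a 2-D ``numpy`` integer array.  All API
coordinates are 0-based ``(row, col)``; only the RLE wire format is 1-based.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import BoundsError, FormatError, RleBoundsError, RleOverlapError

__all__ = [
    "RleRecord",
    "DetectionSet",
    "validate_label_mask",
    "decode_rle",
    "encode_rle",
    "centroids_to_mask",
    "read_mask_image",
    "write_mask_image",
    "read_rle_csv",
    "write_rle_csv",
    "read_detections",
    "write_detections",
    "load_mask_directory",
]


@dataclass(frozen=True)
class RleRecord:
    """One run-length-encoded instance.

    ``runs`` is a sequence of ``(start, length)`` pairs with 1-based
    column-major pixel starts, strictly increasing and non-overlapping.
    """

    image_id: str
    instance_id: int
    runs: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if self.instance_id <= 0:
            raise ValueError(f"instance_id must be positive, got {self.instance_id}")
        prev_end = 0
        for start, length in self.runs:
            if start <= prev_end:
                raise ValueError(
                    f"runs must be strictly increasing and non-overlapping "
                    f"(start {start} after pixel {prev_end})"
                )
            if length <= 0:
                raise ValueError(f"run length must be positive, got {length}")
            prev_end = start + length - 1


@dataclass(frozen=True)
class DetectionSet:
    """Detected points for one image: ``(row, col)`` centroids, 0-based.

    ``confidences`` and ``class_labels``, when present, are parallel to
    ``points``.
    """

    image_id: str
    points: tuple[tuple[int, int], ...]
    confidences: tuple[float, ...] | None = None
    class_labels: tuple[str, ...] | None = None

    def __post_init__(self):
        for name in ("confidences", "class_labels"):
            val = getattr(self, name)
            if val is not None and len(val) != len(self.points):
                raise ValueError(f"{name} must parallel points")


def validate_label_mask(mask: np.ndarray) -> np.ndarray:
    """Check that ``mask`` is a valid 2-D label mask and return it as an array.

    Instance ids need not be contiguous or start at 1 — gaps are fine — but
    every value must be a nonnegative integer.
    """
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise FormatError(f"label mask must be 2-D, got shape {arr.shape}")
    if arr.dtype.kind not in "iu":
        raise FormatError(f"label mask must be integer-typed, got {arr.dtype}")
    if arr.size and arr.min() < 0:
        raise FormatError("label mask values must be >= 0")
    return arr


# ---------------------------------------------------------------------------
# Run-length encoding (Kaggle DSB2018 dialect)
# ---------------------------------------------------------------------------

def decode_rle(
    records: Sequence[RleRecord], height: int, width: int
) -> np.ndarray:
    """Decode run-length records into a label mask.

    Pixel order is the Kaggle dialect: 1-based, column-major (top to bottom
    down each column).  Distinct instances claiming the same pixel raise
    :class:`RleOverlapError`; a run past ``height * width`` raises
    :class:`RleBoundsError`.
    """
    area = height * width
    flat = np.zeros(area, dtype=np.int32)
    for rec in records:
        for start, length in rec.runs:
            lo, hi = start - 1, start - 1 + length
            if lo < 0 or hi > area:
                raise RleBoundsError(
                    f"run ({start}, {length}) of instance {rec.instance_id} "
                    f"exceeds image area {height}x{width}"
                )
            claimed = flat[lo:hi]
            clash = claimed[(claimed != 0) & (claimed != rec.instance_id)]
            if clash.size:
                raise RleOverlapError(
                    f"instances {int(clash[0])} and {rec.instance_id} overlap "
                    f"in image {rec.image_id!r}"
                )
            flat[lo:hi] = rec.instance_id
    return flat.reshape((height, width), order="F")


def encode_rle(mask: np.ndarray, image_id: str = "") -> list[RleRecord]:
    """Encode a label mask into canonical run-length records.

    Canonical means: instances sorted by id, runs sorted by start and
    maximal (no two adjacent runs can be merged).  Inverse of
    :func:`decode_rle`.
    """
    arr = validate_label_mask(mask)
    flat = arr.ravel(order="F")
    records = []
    for inst in np.unique(flat):
        if inst == 0:
            continue
        # 1-based positions of this instance's pixels, column-major
        pos = np.flatnonzero(flat == inst) + 1
        breaks = np.flatnonzero(np.diff(pos) > 1)
        starts = pos[np.r_[0, breaks + 1]]
        ends = pos[np.r_[breaks, len(pos) - 1]]
        runs = tuple((int(s), int(e - s + 1)) for s, e in zip(starts, ends))
        records.append(RleRecord(image_id=image_id, instance_id=int(inst), runs=runs))
    return records


def _runs_to_string(runs: Sequence[tuple[int, int]]) -> str:
    return " ".join(f"{s} {l}" for s, l in runs)


def _runs_from_string(text: str) -> tuple[tuple[int, int], ...]:
    tokens = text.split()
    if len(tokens) % 2:
        raise FormatError(f"odd number of RLE tokens in {text!r}")
    it = iter(int(t) for t in tokens)
    return tuple(zip(it, it))


def read_rle_csv(path: str | Path) -> dict[str, list[RleRecord]]:
    """Read a Kaggle submission CSV (``ImageId``, ``EncodedPixels``).

    Each row is one instance; instance ids are assigned 1..k in row order
    within each image (the format itself carries no ids).
    """
    df = pd.read_csv(path, dtype={"ImageId": str, "EncodedPixels": str})
    for col in ("ImageId", "EncodedPixels"):
        if col not in df.columns:
            raise FormatError(f"submission CSV missing column {col!r}")
    out: dict[str, list[RleRecord]] = {}
    for image_id, group in df.groupby("ImageId", sort=False):
        recs = []
        for i, enc in enumerate(group["EncodedPixels"], start=1):
            if not isinstance(enc, str) or not enc.strip():
                continue  # empty-prediction row
            recs.append(RleRecord(image_id=image_id, instance_id=i,
                                  runs=_runs_from_string(enc)))
        out[image_id] = recs
    return out


def write_rle_csv(path: str | Path, masks: Mapping[str, np.ndarray]) -> None:
    """Encode label masks and write a Kaggle submission CSV.

    An image with no instances gets a single row with empty EncodedPixels,
    so every image id stays present in the file.
    """
    rows = []
    for image_id in masks:
        records = encode_rle(masks[image_id], image_id=image_id)
        if not records:
            rows.append({"ImageId": image_id, "EncodedPixels": ""})
        for rec in records:
            rows.append({"ImageId": image_id,
                         "EncodedPixels": _runs_to_string(rec.runs)})
    pd.DataFrame(rows, columns=["ImageId", "EncodedPixels"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Detection centroids
# ---------------------------------------------------------------------------

def centroids_to_mask(
    dets: DetectionSet, height: int, width: int, half_size: int = 15
) -> np.ndarray:
    """Rasterise detection centroids into a label mask.

    Each point becomes an axis-aligned square of side ``2*half_size + 1``
    clipped to the image, labelled with a fresh id (1..n in point order).
    Later points overwrite earlier ones on contested pixels, which makes the
    result deterministic given the input order.  Instance id i corresponds
    to point i-1, so confidences can be carried across.
    """
    if half_size < 0:
        raise ValueError("half_size must be >= 0")
    mask = np.zeros((height, width), dtype=np.int32)
    for i, (r, c) in enumerate(dets.points, start=1):
        if not (0 <= r < height and 0 <= c < width):
            raise BoundsError(
                f"point ({r}, {c}) outside {height}x{width} image "
                f"{dets.image_id!r}"
            )
        r0, r1 = max(0, r - half_size), min(height, r + half_size + 1)
        c0, c1 = max(0, c - half_size), min(width, c + half_size + 1)
        mask[r0:r1, c0:c1] = i
    return mask


def read_detections(path: str | Path) -> dict[str, DetectionSet]:
    """Read detection centroids from JSON.

    Expected schema (this package's own)::

        {"images": [{"image_id": "...",
                     "points": [[row, col], ...],
                     "confidences": [...],      # optional
                     "class_labels": [...]}]}   # optional
    """
    with open(path) as fh:
        doc = json.load(fh)
    if not isinstance(doc, dict) or "images" not in doc:
        raise FormatError("detection JSON must be an object with an 'images' list")
    out = {}
    for entry in doc["images"]:
        ds = DetectionSet(
            image_id=str(entry["image_id"]),
            points=tuple((int(r), int(c)) for r, c in entry["points"]),
            confidences=(tuple(float(x) for x in entry["confidences"])
                         if "confidences" in entry else None),
            class_labels=(tuple(str(x) for x in entry["class_labels"])
                          if "class_labels" in entry else None),
        )
        out[ds.image_id] = ds
    return out


def write_detections(path: str | Path, dets: Mapping[str, DetectionSet]) -> None:
    images = []
    for ds in dets.values():
        entry: dict = {"image_id": ds.image_id,
                       "points": [list(p) for p in ds.points]}
        if ds.confidences is not None:
            entry["confidences"] = list(ds.confidences)
        if ds.class_labels is not None:
            entry["class_labels"] = list(ds.class_labels)
        images.append(entry)
    with open(path, "w") as fh:
        json.dump({"images": images}, fh, indent=1)


# ---------------------------------------------------------------------------
# Label images
# ---------------------------------------------------------------------------

_TIFF_SUFFIXES = {".tif", ".tiff"}
_PNG_SUFFIXES = {".png"}


def read_mask_image(path: str | Path) -> np.ndarray:
    """Read a single-channel integer label image (TIFF or PNG)."""
    path = Path(path)
    if path.suffix.lower() in _TIFF_SUFFIXES:
        import tifffile

        arr = tifffile.imread(path)
    elif path.suffix.lower() in _PNG_SUFFIXES:
        import imageio.v3 as iio

        arr = iio.imread(path)
    else:
        raise FormatError(f"unsupported label image suffix {path.suffix!r} "
                          f"(use .tif/.tiff/.png)")
    if arr.ndim != 2:
        raise FormatError(
            f"{path.name}: label images must be single-channel 2-D, "
            f"got shape {arr.shape}"
        )
    if arr.dtype.kind == "f":
        raise FormatError(f"{path.name}: float images are not label masks")
    return validate_label_mask(arr.astype(np.int64))


def write_mask_image(mask: np.ndarray, path: str | Path) -> None:
    """Write a label mask losslessly as TIFF or PNG.

    PNG supports at most 16-bit labels; larger ids require TIFF.
    """
    arr = validate_label_mask(mask)
    path = Path(path)
    maxv = int(arr.max()) if arr.size else 0
    if path.suffix.lower() in _TIFF_SUFFIXES:
        import tifffile

        dtype = np.uint16 if maxv < 2**16 else np.uint32
        tifffile.imwrite(path, arr.astype(dtype))
    elif path.suffix.lower() in _PNG_SUFFIXES:
        import imageio.v3 as iio

        if maxv >= 2**16:
            raise FormatError(
                f"label id {maxv} does not fit 16-bit PNG; use TIFF"
            )
        dtype = np.uint8 if maxv < 2**8 else np.uint16
        iio.imwrite(path, arr.astype(dtype))
    else:
        raise FormatError(f"unsupported label image suffix {path.suffix!r}")


def load_mask_directory(directory: str | Path) -> dict[str, np.ndarray]:
    """Load every TIFF/PNG label image in a directory, keyed by file stem."""
    directory = Path(directory)
    out = {}
    for path in sorted(directory.iterdir()):
        if path.suffix.lower() in _TIFF_SUFFIXES | _PNG_SUFFIXES:
            out[path.stem] = read_mask_image(path)
    return out
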