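"""Leaderboard analysis: how the choice of metric reshuffles a ranking.

Scores many submissions under many metric specs into a submissions x specs
matrix, correlates the score columns (Pearson on raw scores, or Spearman on
ranks), and reports per-submission rank displacements between two metric
interpretations.  The score matrix and correlation matrix are plain pandas
DataFrames (submission ids as index, canonical spec strings as columns) so
they write straight to CSV.

A submission that cannot be scored under some spec (for example a
curve-based metric without confidences) gets NaN in the matrix — an
explicit missing marker, never a silent drop; correlations exclude missing
values pairwise.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dataset import ImagePair
from .errors import InsufficientDataError, SegscoreError
from .notation import MetricSpec, evaluate_spec, format_spec, parse_spec

__all__ = [
    "score_submissions",
    "correlate",
    "rank_shifts",
    "ranks",
    "plot_correlation_heatmap",
]

SubmissionData = Mapping[str, object]  # image id -> mask or (mask, confidences)


def _as_pair(gt_mask, entry) -> ImagePair:
    if isinstance(entry, tuple):
        pred, conf = entry
        return ImagePair(gt=gt_mask, pred=pred, confidences=conf)
    return ImagePair(gt=gt_mask, pred=entry)


def build_dataset(
    gt: Mapping[str, np.ndarray], submission: SubmissionData
) -> list[ImagePair]:
    """Pair a submission against the ground truth, image by image.

    A ground-truth image the submission does not cover counts as an empty
    prediction; an image id the ground truth does not know is an error.
    """
    unknown = sorted(set(submission) - set(gt))
    if unknown:
        raise SegscoreError(
            f"submission contains unknown image ids: {unknown}"
        )
    pairs = []
    for iid in sorted(gt):
        if iid in submission:
            pair = _as_pair(gt[iid], submission[iid])
        else:
            pair = ImagePair(gt=gt[iid], pred=np.zeros_like(gt[iid]),
                             confidences={})
        pair.image_id = iid
        pairs.append(pair)
    return pairs


def score_submissions(
    gt: Mapping[str, np.ndarray],
    submissions: Mapping[str, SubmissionData],
    specs: Sequence[MetricSpec | str],
    empty_score: float = 1.0,
) -> pd.DataFrame:
    """Score every submission under every metric spec.

    Returns a DataFrame indexed by submission id with one column per
    canonical spec string; cell (i, j) is ``evaluate_spec(spec_j, gt vs
    submission_i)``.  Deterministic given the inputs.
    """
    parsed = [parse_spec(s) if isinstance(s, str) else s for s in specs]
    columns = [format_spec(s) for s in parsed]
    rows = {}
    for sid in submissions:
        dataset = build_dataset(gt, submissions[sid])
        row = []
        for spec in parsed:
            try:
                row.append(evaluate_spec(spec, dataset, empty_score))
            except SegscoreError:
                row.append(np.nan)
        rows[sid] = row
    return pd.DataFrame.from_dict(rows, orient="index", columns=columns)


def correlate(matrix: pd.DataFrame, method: str = "pearson") -> pd.DataFrame:
    """Cross-correlation matrix of the metric columns.

    ``method`` is ``"pearson"`` (product-moment on raw scores) or
    ``"spearman"`` (rank-based).  Missing scores are excluded pairwise; a
    zero-variance column yields NaN against everything (a defined missing
    marker).  Requires at least two submissions.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"method must be 'pearson' or 'spearman', got {method!r}")
    if len(matrix) < 2:
        raise InsufficientDataError(
            f"correlation needs >= 2 submissions, got {len(matrix)}"
        )
    return matrix.corr(method=method)


def ranks(matrix: pd.DataFrame, spec: str) -> pd.Series:
    """Leaderboard ranks (1 = best) under one metric column.

    Scores sort descending; ties break by submission id, so ranks are a
    permutation and displacements are well defined.
    """
    if spec not in matrix.columns:
        raise SegscoreError(f"spec {spec!r} not in score matrix columns")
    order = sorted(matrix.index, key=lambda sid: (-matrix.at[sid, spec], sid))
    return pd.Series({sid: r for r, sid in enumerate(order, start=1)},
                     name=spec).reindex(matrix.index)


def rank_shifts(
    matrix: pd.DataFrame, spec_a: str, spec_b: str
) -> tuple[pd.DataFrame, dict]:
    """Signed per-submission rank displacement between two metric columns.

    Returns a DataFrame with columns ``rank_a``, ``rank_b`` and ``shift``
    (= rank_b - rank_a; positive means the submission drops down the
    leaderboard under spec_b), plus a summary dict with ``max_abs_shift``
    and ``n_shifted``.
    """
    ra = ranks(matrix, spec_a)
    rb = ranks(matrix, spec_b)
    df = pd.DataFrame({"rank_a": ra, "rank_b": rb, "shift": rb - ra})
    summary = {
        "max_abs_shift": int(df["shift"].abs().max()),
        "n_shifted": int((df["shift"] != 0).sum()),
    }
    return df, summary


def plot_correlation_heatmap(corr: pd.DataFrame, path) -> None:
    """Write a correlation heatmap image (one panel of the cross-metric
    correlation figure style)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(max(4, 0.5 * len(corr.columns)) + 2,) * 2
    )
    im = ax.imshow(corr.values, vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(corr.columns)))
    ax.set_xticklabels(corr.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(corr.index)))
    ax.set_yticklabels(corr.index, fontsize=7)
    fig.colorbar(im, ax=ax, shrink=0.8)
    ax.set_title("Metric cross-correlation")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
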