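"""Independent brute-force oracles.

Everything here is written with explicit Python pixel sets, exhaustive
enumeration and hand-summed means — deliberately sharing no code with the
package — so that agreement between the two routes is evidence, not
tautology.  The unique-partner matching oracle is valid for IoU thresholds
at or above 0.5, where a qualifying partner is provably unique.
"""

from __future__ import annotations

import itertools

import numpy as np


def pixel_sets(mask):
    """id -> set of (row, col) pixel tuples."""
    out = {}
    for r in range(mask.shape[0]):
        for c in range(mask.shape[1]):
            v = int(mask[r, c])
            if v > 0:
                out.setdefault(v, set()).add((r, c))
    return out


def iou_table(gt, pred):
    """Set-based IoU for every overlapping (gt, pred) instance pair."""
    gsets, psets = pixel_sets(gt), pixel_sets(pred)
    table = {}
    for gi, gs in gsets.items():
        for pi, ps in psets.items():
            inter = len(gs & ps)
            if inter:
                table[(gi, pi)] = inter / len(gs | ps)
    return table


def unique_match(gt, pred, threshold, strict=True):
    """Matching oracle for thresholds >= 0.5: collect the qualifying pairs
    directly (each instance has at most one partner above half-overlap) and
    verify that uniqueness on the way."""
    assert threshold >= 0.5
    table = iou_table(gt, pred)
    pairs = [(g, p, v) for (g, p), v in table.items()
             if (v > threshold if strict else v >= threshold)]
    assert len({g for g, _, _ in pairs}) == len(pairs), "gt partner not unique"
    assert len({p for _, p, _ in pairs}) == len(pairs), "pred partner not unique"
    gt_ids = set(pixel_sets(gt))
    pred_ids = set(pixel_sets(pred))
    fn = gt_ids - {g for g, _, _ in pairs}
    fp = pred_ids - {p for _, p, _ in pairs}
    return sorted(pairs), fn, fp


def optimal_match(gt, pred, threshold, strict=True):
    """Exhaustive maximum-total-IoU one-to-one assignment (any threshold).

    Enumerates every injective gt->pred mapping over the qualifying pairs;
    feasible only for small instance counts.
    """
    table = iou_table(gt, pred)
    qual = {k: v for k, v in table.items()
            if (v > threshold if strict else v >= threshold)}
    gt_ids = sorted({g for g, _ in qual})
    pred_ids = sorted({p for _, p in qual})
    best_total, best_pairs = -1.0, []
    for k in range(min(len(gt_ids), len(pred_ids)), -1, -1):
        for gsub in itertools.combinations(gt_ids, k):
            for psub in itertools.permutations(pred_ids, k):
                if all((g, p) in qual for g, p in zip(gsub, psub)):
                    total = sum(qual[(g, p)] for g, p in zip(gsub, psub))
                    if total > best_total + 1e-15:
                        best_total = total
                        best_pairs = sorted(
                            (g, p, qual[(g, p)]) for g, p in zip(gsub, psub)
                        )
    return best_pairs, max(best_total, 0.0)


def counts_for(gt, pred, threshold, strict=True):
    pairs, fn, fp = unique_match(gt, pred, threshold, strict)
    return len(pairs), len(fp), len(fn)


# --- hand-written metric formulas on (tp, fp, fn) triples ------------------

def ts_of(tp, fp, fn, empty=1.0):
    return tp / (tp + fp + fn) if tp + fp + fn else empty


def f1_of(tp, fp, fn, empty=1.0):
    return 2 * tp / (2 * tp + fp + fn) if tp + fp + fn else empty


def prec_of(tp, fp, fn, empty=1.0):
    if tp + fp:
        return tp / (tp + fp)
    return empty if tp + fp + fn == 0 else 0.0


def rec_of(tp, fp, fn, empty=1.0):
    if tp + fn:
        return tp / (tp + fn)
    return empty if tp + fp + fn == 0 else 0.0


def digits_of(tp, fp, fn, empty=1.0):
    return prec_of(tp, fp, fn, empty) * rec_of(tp, fp, fn, empty)


def pq_of(pairs, n_fp, n_fn):
    tp = len(pairs)
    denom = tp + (n_fp + n_fn) / 2
    return sum(v for _, _, v in pairs) / denom if denom else 0.0


# --- brute-force PR curve and AP1 ------------------------------------------

def pr_points(scored, n_gt):
    """Exhaustive cutoff enumeration: ``scored`` is [(confidence, is_tp)].

    For every distinct confidence value c (descending) count predictions
    with confidence >= c and emit (recall, precision).
    """
    cutoffs = sorted({c for c, _ in scored}, reverse=True)
    points = []
    for cut in cutoffs:
        sel = [t for c, t in scored if c >= cut]
        tp = sum(sel)
        points.append((tp / n_gt if n_gt else 0.0, tp / len(sel)))
    return points


def envelope_area(points):
    """Exact area under the monotone precision envelope over recall [0,1]."""
    if not points:
        return 0.0
    area, prev_r = 0.0, 0.0
    for i, (r, _) in enumerate(points):
        env = max(p for _, p in points[i:])
        area += (r - prev_r) * env
        prev_r = r
    return area


def ap1_bruteforce(images, threshold):
    """AP1 oracle: unique-partner matching per image (t >= 0.5), pooled
    cutoff enumeration, exact envelope integration.  ``images`` is a list of
    (gt, pred, confidences)."""
    scored, n_gt = [], 0
    for gt, pred, conf in images:
        pairs, _, _ = unique_match(gt, pred, threshold)
        tp_ids = {p for _, p, _ in pairs}
        n_gt += len(pixel_sets(gt))
        for pid in pixel_sets(pred):
            scored.append((conf[pid], pid in tp_ids))
    if not scored:
        return 0.0
    return envelope_area(pr_points(scored, n_gt))


# --- dataset-level variant oracle ------------------------------------------

def evaluate_bruteforce(base, mode, thresholds, images, empty=1.0):
    """Hand-summed evaluation of every catalogued metric variant.

    ``images`` is a list of (gt, pred, confidences); ``thresholds`` a list
    of IoU thresholds >= 0.5.  Mirrors the dispatch table with explicit
    loops and the set-based primitives above.
    """
    def counts(img, t):
        return counts_for(img[0], img[1], t)

    def pooled(t):
        tp = fp = fn = 0
        for img in images:
            a, b, c = counts(img, t)
            tp, fp, fn = tp + a, fp + b, fn + c
        return tp, fp, fn

    def simple(fn_of, t):
        if mode == "agg":
            return fn_of(*pooled(t), empty)
        vals = [fn_of(*counts(img, t), empty) for img in images]
        return sum(vals) / len(vals)

    def mean_over_thresholds(f):
        vals = [f(t) for t in thresholds]
        return sum(vals) / len(vals)

    simple_map = {"TS": ts_of, "F1": f1_of, "precision": prec_of,
                  "recall": rec_of, "AP2": ts_of, "mAP4": digits_of}
    if base in simple_map:
        return mean_over_thresholds(lambda t: simple(simple_map[base], t))
    if base == "PQ":
        def pq_at(t):
            if mode == "agg":
                all_pairs, fp_n, fn_n = [], 0, 0
                for img in images:
                    pairs, fns, fps = unique_match(img[0], img[1], t)
                    all_pairs += pairs
                    fn_n += len(fns)
                    fp_n += len(fps)
                return pq_of(all_pairs, fp_n, fn_n)
            vals = []
            for img in images:
                pairs, fns, fps = unique_match(img[0], img[1], t)
                vals.append(pq_of(pairs, len(fps), len(fns)))
            return sum(vals) / len(vals)
        return mean_over_thresholds(pq_at)
    if base in ("AP1", "AP4"):
        def ap_at(t):
            if mode == "agg":
                return ap1_bruteforce(images, t)
            vals = [ap1_bruteforce([img], t) for img in images]
            return sum(vals) / len(vals)
        return mean_over_thresholds(ap_at)
    if base == "AP3":
        if mode == "agg":
            return mean_over_thresholds(lambda t: prec_of(*pooled(t), empty))
        vals = []
        for img in images:
            per = [prec_of(*counts(img, t), empty) for t in thresholds]
            vals.append(sum(per) / len(per))
        return sum(vals) / len(vals)
    if base == "mAP2":
        if mode == "agg":
            return mean_over_thresholds(lambda t: ts_of(*pooled(t), empty))
        base = "mAP5"  # image mean of per-image threshold-mean, below
    if base == "mAP3":
        vals = []
        for img in images:
            per = [prec_of(*counts(img, t), empty) for t in thresholds]
            vals.append(sum(per) / len(per))
        return sum(vals) / len(vals)
    if base == "mAP5":
        vals = []
        for img in images:
            per = [ts_of(*counts(img, t), empty) for t in thresholds]
            vals.append(sum(per) / len(per))
        return sum(vals) / len(vals)
    if base in ("mAP1", "mAP6"):
        # single implicit class: class mean == pooled AP over thresholds
        def ap_at(t):
            return ap1_bruteforce(images, t)
        return mean_over_thresholds(ap_at)
    raise AssertionError(f"oracle has no route for {base}")
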