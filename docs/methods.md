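# Methods

## Matching model

All object-level scores start from the same primitive.  Given a
ground-truth label mask and a predicted label mask for one image (2-D
integer grids, 0 = background, every positive id one instance, ids not
required to be contiguous), segscore computes the IoU of every
overlapping instance pair as exact pixel counts followed by one division
— there is no floating accumulation in the IoU itself.  A pair qualifies
at threshold *t* when IoU > *t*; the comparison is strict by default
because that is the convention most challenge texts state, and a
`strict_iou=False` switch provides `>=` for parity with tools that use
it.  The two conventions differ exactly on pairs whose IoU sits on the
threshold (an IoU of exactly 0.5 is common for small axis-aligned
objects, so the choice is observable; `examples/metric_zoo.py` shows a
case).

Matching is one-to-one.  For *t* ≥ 0.5 at most one prediction can
qualify per ground-truth instance and vice versa (two sets each sharing
more than half of their union with a third would overlap each other), so
the matching is forced and any algorithm returns it.  For *t* < 0.5,
where the paper trail gives no rule, segscore maximises total matched
IoU with `scipy.optimize.linear_sum_assignment` over the qualifying
pairs; candidate ids are processed in sorted order so the result is
deterministic.  Confidence-swept PR curves use a different, deliberately
greedy matcher: predictions take ground truth in descending confidence
order, so a prediction's TP/FP status never depends on predictions
ranked below it — the property a PR curve needs to be internally
consistent.  Above 0.5 the two matchers provably coincide.

## Metrics

With counts TP/FP/FN per image (or pooled):

* precision = TP/(TP+FP), recall = TP/(TP+FN),
  F1 = 2TP/(2TP+FP+FN), threat score TS = TP/(TP+FP+FN);
* Digits score = precision · recall;
* panoptic quality PQ = (Σ matched IoU)/(TP + (FP+FN)/2).  PQ factorises
  as (mean matched IoU) × F1, so PQ ≤ F1 always; it is **not** bounded by
  TS in general, since PQ's denominator halves the detection penalty.
* AP1 = area under the precision–recall curve built by sweeping the
  prediction-confidence cutoff from high to low, one point per distinct
  cutoff, counts pooled across the supplied images.

AP1's integral is ambiguous in the literature, so both readings are
implemented: the default integrates the monotone non-increasing
precision envelope exactly (PASCAL 2010+ practice), `coco_101` samples
the envelope at 101 evenly spaced recalls, and `envelope=False`
integrates the raw curve.  The numbered historical variants are
compositions of these atoms with three averaging combinators (over IoU
thresholds, over images, over classes):

| variant | composition |
|---------|-------------|
| AP1 / mAP1 | PR-curve area / its class mean |
| AP2 | threat score at a fixed threshold |
| mAP2 | threshold mean of aggregated AP2 |
| AP3 / mAP3 | threshold mean of aggregated precision / its image mean |
| mAP4 | precision × recall |
| mAP5 | image mean of per-image mAP2 |
| AP4 | threshold mean of AP1 ("COCO metric") |
| mAP6 | class mean of AP4 |

mAP1 and mAP6 share a routing (class mean of threshold-averaged pooled
AP1) and differ only in the conventional threshold set — a single value
versus a range; the notation makes the distinction, not the code path.
`mAP2_avg` is routed as mAP5, which is its image-averaged reading by
definition; mAP3 and mAP5 are inherently image-averaged, and the mode
token is accepted for grammar uniformity but the definition governs.

### Degenerate counts

Averaged-by-image scores are sensitive to what 0/0 means, so the
conventions are explicit parameters rather than buried constants: an
image with empty ground truth **and** empty prediction scores
`empty_score` (default 1.0 — predicting nothing where there is nothing
is perfect) for all simple metrics and contributes nothing to pooled
counts; any other vanishing denominator scores 0 (no predictions →
precision 0 when objects exist; no objects → recall 0 when predictions
exist).  PQ with an all-empty match result scores 0.  An empty PR curve
(no predictions anywhere) has AP 0.

### Threshold grids

`ThresholdRange(start, stop, step)` materialises its values by rounding
onto the step grid (`round(start + k·step, 10)`) so the canonical range
0.5:0.05:0.95 contains exactly 0.95 rather than 0.9500000000000004; both
endpoints are inclusive, all values must lie in [0, 1).  A single
threshold is the degenerate range start = stop.

## Notation

The grammar is `[px:]<base>_<agg|avg>^<t|start:step:stop>`, with
`@IoU=...` accepted as an input alias for `^` and whitespace ignored.
`parse` and `format` are mutually inverse on the canonical grammar
(property-tested).  `AP` and `mAP` without a variant number are rejected
with guidance: an ambiguous name is an error, not a default.  The pixel
prefix is valid only for the simple confusion metrics, which are the
ones with a meaningful pixel-level reading.

## Leaderboard analysis

`score_submissions` produces a submissions × specs DataFrame; a
submission missing an image is scored as an empty prediction for that
image, and a submission that cannot be scored under a spec (e.g. a
curve metric without confidences) gets NaN — visible, never dropped.
Correlation is `DataFrame.corr` with pairwise NaN exclusion, Pearson or
Spearman.  Pearson is the classical product-moment choice for score
columns; rank-based statements in the tests use Spearman because the
F1/TS relation F1 = 2·TS/(1+TS) is strictly monotone but nonlinear —
their Spearman correlation is exactly 1 while Pearson is generically
slightly below 1.  Ranks sort scores descending with ties broken by
submission id, so rank displacement between two specs is well defined.

## Synthetic data generator

The generator emulates the structural features of segmentation-challenge
data that the metrics are sensitive to, and nothing else: many
non-overlapping blob-like instances per image (random ellipses or
rectangles, diameter 10–24 px by default on 256×256 images, ≥ 2 px
apart, placed by rejection sampling with a capacity error naming the
achievable count when the request cannot fit), and submissions that are
the ground truth degraded through three orthogonal channels — drops
(→ FN), spurious background objects (→ FP, Poisson counts), and jitter
(integer shifts plus random dilation/erosion, → depressed IoU).
Confidence values are the true IoU plus clipped Gaussian noise
(σ = 0.1 by default), so confidence ranking is informative but
imperfect, which makes PR curves non-trivial.

Cohorts derive all randomness from one seed through
`numpy.random.SeedSequence` substreams keyed by (seed, image index) and
(seed, submission index, image index): runs are byte-identical, and
adding images or submissions never perturbs earlier ones.  The `nested`
cohort mode drops objects along one fixed per-image order with no jitter,
making every submission's error set a superset of all better ones — a
control for which every fixed-threshold metric provably produces the
same ranking.

What the generator does **not** emulate: intensity images, realistic
cell morphology, touching/overlapping instances, annotation noise in the
ground truth, or correlated errors across a submission.  Passing tests
therefore demonstrate correctness of the metric computations and the
qualitative mechanisms (aggregation divergence, threshold sensitivity,
rank reshuffling), not performance claims about any real challenge.

## Problem sizes

The test suite and the acceptance script run on deliberately small
scenes — 96×96 images with ~8 objects for cohort experiments, 48×48 with
≤ 8 objects for the 200-trial oracle comparisons — chosen so the whole
suite completes in well under a minute while every code path (including
the exhaustive brute-force oracles) is exercised.  The metric
computations are size-independent integer arithmetic, so nothing about
the scores depends on these sizes.

## Verification strategy

Every metric variant is recomputed by an independent route in the tests:
pixel sets as Python `set`s, qualifying pairs collected directly (valid
above IoU 0.5 by the uniqueness argument), exhaustive PR-cutoff
enumeration, envelope integration by scanning, and hand-summed means.
The two routes must agree to 1e-12 across randomized scenes.  The
sub-0.5 assignment is checked against exhaustive enumeration of all
injective matchings on small instances.  Known limitation: the
brute-force oracles do not cover multi-class datasets (the class
combinator is exercised against hand-built two-class scenes instead).
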