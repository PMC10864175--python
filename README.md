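# segscore

Unambiguous evaluation metrics for instance segmentation and object
detection in bioimage analysis.

## The problem

Quantitative benchmarks in cell and nuclei segmentation lean on a small
set of object-level scores: a prediction counts as a true positive (TP)
when its intersection-over-union with a ground-truth instance exceeds an
IoU threshold, and the resulting TP/FP/FN counts feed a formula.  The
trouble is the names.  At least six incompatible computations circulate
under "AP" or "mAP": the classical area under the confidence-swept
precision–recall curve, the threat score TP/(TP+FP+FN), precision or AP
averaged over IoU thresholds, per-image averages of any of these, class
means, and combinations.  Two papers can report "mAP = 0.62" and mean
different quantities; two challenge leaderboards can reorder visibly when
the interpretation changes.

segscore implements every member of that family **behind an explicit
notation** that pins down each ambiguous axis:

```
TS_agg^0.5:0.05:0.95     threat score, counts pooled over the dataset,
                         averaged over IoU thresholds 0.5, 0.55, ..., 0.95
F1_avg^0.5               F1 at IoU 0.5, computed per image and averaged
px:recall_agg^0.5        pixel-level recall (object/pixel is explicit too)
```

The bare tokens `AP` and `mAP` are rejected by the parser on purpose; the
historical interpretations remain reachable as explicitly numbered
variants (`AP1`..`AP4`, `mAP1`..`mAP6`) so comparison studies can name
them precisely.

## What is in the box

| module        | contents |
|---------------|----------|
| `instance_io` | label-image TIFF/PNG I/O, Kaggle run-length-encoded submission CSVs (1-based, column-major), detection-centroid JSON, conversions between them |
| `matching`    | exact pairwise IoU, one-to-one TP/FP/FN matching at an IoU threshold (strict `>` by default, `>=` optional), confidence-priority matching for PR curves, pixel-level confusion counts |
| `metrics`     | precision, recall, F1, threat score, panoptic quality PQ = ΣIoU/(TP+(FP+FN)/2), PR curves and AP (PASCAL all-points or COCO 101-point interpolation), the "Digits score" p·r, and threshold/image/class averaging combinators |
| `notation`    | `parse_spec` / `format_spec` for the explicit grammar, `evaluate_spec` dispatching any spec to the engine |
| `leaderboard` | submissions × specs score matrices, Pearson/Spearman cross-metric correlation, per-submission rank-shift analysis |
| `synthgen`    | reproducible synthetic ground truth (non-overlapping ellipses/rectangles) and degraded "submissions" with controllable drop, spurious-object and boundary-jitter rates plus confidence models |
| `cli`         | `segscore evaluate`, `segscore leaderboard`, `segscore simulate` |

## A worked example

Two images, unbalanced object counts: a crowded image where 9 of 10
objects are found with 1 spurious prediction, and a sparse image whose
single object is missed (`examples/aggregated_vs_averaged.py`):

```python
import numpy as np
from segscore import ImagePair, evaluate_spec

dataset = [crowded, sparse]          # ImagePairs built in the example
evaluate_spec("TS_agg^0.5", dataset) # -> 0.7500
evaluate_spec("TS_avg^0.5", dataset) # -> 0.4091
```

Pooling counts over the dataset gives TS = 9/12 = 0.75; computing the
identical formula per image and averaging gives (9/11 + 0)/2 = 9/22 ≈
0.41.  Same predictions, same formula, same threshold — the aggregation
mode alone moves the score by 0.34, which is why it belongs in the
metric's name.

`examples/leaderboard_correlation.py` runs the full experiment at desk
scale: a 10-image synthetic dataset, 20 submissions of monotonically
decreasing quality, six metric interpretations.  Output from a run with
seed 1:

```
Spearman rank correlation between metric columns:
                      TS_agg^0.5  F1_agg^0.5  TS_avg^0.5  TS_agg^0.9  TS_agg^0.5:0.05:0.95  PQ_agg^0.5
TS_agg^0.5                 1.000       1.000       0.998       0.881                 0.986       0.997
...
TS_agg^0.5 -> F1_agg^0.5: 0 submissions change rank (deterministically related at a fixed threshold)
TS_agg^0.5 -> TS_agg^0.9: 11 submissions change rank, max displacement 8 positions
```

Three things to read off: F1 and the threat score at one shared fixed
threshold order any cohort identically (F1 = 2·TS/(1+TS) is strictly
monotone, so their rank correlation is exactly 1); a fixed IoU threshold
of 0.9 correlates worst with everything else; and even columns
correlating at 0.98+ move submissions several positions on the board.

`examples/metric_zoo.py` prints eleven differently-named scores for one
small scene — they range from 0.11 to 0.56 on the same prediction.

## Command line

```bash
segscore evaluate --gt gt_dir/ --pred pred_dir/ --spec "TS_agg^0.5:0.05:0.95"
segscore leaderboard --gt gt_dir/ --submissions subs/ --specs specs.txt --corr pearson --out results/
segscore simulate --config sim.yaml --out fixtures/
```

`evaluate` accepts label-image directories or Kaggle RLE CSVs;
`leaderboard` writes `scores.csv`, `correlation.csv` and
`rank_shifts.csv`; `simulate` writes a reproducible synthetic fixture
tree (TIFF masks + RLE CSV + confidence JSON) and echoes the fully
resolved configuration.

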