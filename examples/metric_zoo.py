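"""Tour of the metric variants on one small hand-built scene.

Builds a ground truth of three blobs and a prediction that finds two of
them (one with a sloppy boundary), misses one, and adds a spurious blob —
then prints every metric interpretation by its explicit notation string.
The point: identical data, one "AP-like" family, very different numbers.
"""

import numpy as np

from segscore import ImagePair, evaluate_spec

# ground truth: three 6x6 square objects
gt = np.zeros((32, 48), dtype=int)
gt[4:10, 4:10] = 1
gt[4:10, 20:26] = 2
gt[20:26, 4:10] = 3

# prediction: object 1 perfect, object 2 shifted by 2 columns (IoU = 0.5),
# object 3 missed, plus one spurious blob
pred = np.zeros_like(gt)
pred[4:10, 4:10] = 1
pred[4:10, 22:28] = 2
pred[20:26, 36:42] = 9
conf = {1: 0.95, 2: 0.6, 9: 0.8}

dataset = [ImagePair(gt=gt, pred=pred, confidences=conf)]

specs = [
    "TS_agg^0.5",            # threat score at IoU 0.5 (strict '>')
    "TS_agg^0.4",            # the same score one notch looser
    "TS_agg^0.5:0.05:0.95",  # averaged over the canonical threshold range
    "F1_agg^0.5",
    "precision_agg^0.5",
    "recall_agg^0.5",
    "PQ_agg^0.5",            # matched-IoU mass over a detection denominator
    "AP1_agg^0.5",           # confidence-swept area under the PR curve
    "AP4_agg^0.5:0.05:0.95", # the 'COCO metric': AP1 averaged over IoUs
    "mAP4_agg^0.5",          # 'Digits score' = precision x recall
    "px:F1_agg^0.5",         # same name, pixel level: a different quantity
]

print(f"{'spec':<24}score")
for spec in specs:
    print(f"{spec:<24}{evaluate_spec(spec, dataset):.4f}")

print()
print("Note how 'AP-like' numbers on the same prediction span the whole")
print("range above: only the explicit notation says which one is meant.")
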