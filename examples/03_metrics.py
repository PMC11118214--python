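"""Segmentation metrics on a worked pair of masks.

Computes Dice, boundary Hausdorff distance and threshold-free metrics for a
prediction that overlaps half of a ground-truth square, then a paired
t-test between two score lists.
"""

import numpy as np

from agsam.metrics import compare_paired, dice, hausdorff, prob_metrics

gt = np.zeros((16, 16), dtype=int)
gt[4:10, 4:10] = 1            # 6x6 square
pred = np.zeros((16, 16), dtype=int)
pred[4:10, 7:13] = 1          # shifted 3 px right: half overlap

d = dice(pred, gt, 1)
hd, degenerate = hausdorff(pred, gt, 1)
print(f"dice = {d:.4f}  (1.0 is perfect overlap)")
print(f"hausdorff = {hd:.4f} px (max boundary deviation; "
      f"degenerate={degenerate})")

probs = np.stack([1.0 - pred, pred]).astype(float)
pm = prob_metrics(probs, gt, 1)
print(f"sensitivity = {pm.sensitivity:.4f}, specificity = "
      f"{pm.specificity:.4f}")

r = compare_paired([0.62, 0.71, 0.58, 0.69, 0.66],
                   [0.55, 0.68, 0.52, 0.61, 0.60])
print(f"paired t-test: t = {r.t:.3f}, p = {r.p:.4f} ({r.stars})")
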