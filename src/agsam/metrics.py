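"""Segmentation evaluation: Dice, Hausdorff, threshold-free metrics, and
paired significance testing.

Conventions
-----------
* ``dice``: ``2|P∩G| / (|P|+|G|)``; both-empty = 1.0.
* ``hausdorff``: symmetric Hausdorff distance between *boundary* pixel sets
  under the Euclidean metric, in pixels.  Exactly one empty side returns the
  image diagonal and is flagged degenerate (keeps result tables total);
  both empty = 0.
* probability metrics: sensitivity/specificity at the argmax label (ties
  break to the lowest class index, numpy's argmax convention); AUC/AUPR by
  rank integration of the per-pixel class probability against the binary
  ground truth.  A class absent from the ground truth has no defined
  sensitivity/AUC/AUPR; those come back as NaN and are excluded from means.
* ``compare_paired``: paired two-sided t-test on per-image score
  differences (methods are compared on the same test images).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial.distance import directed_hausdorff
from scipy import stats as sstats
from sklearn.metrics import average_precision_score, roc_auc_score

__all__ = ["dice", "hausdorff", "prob_metrics", "compare_paired",
           "evaluate_samples", "evaluate_model", "summarize",
           "PairedComparison"]


def dice(pred_labels: np.ndarray, gt: np.ndarray, cls: int) -> float:
    """Overlap coefficient of class ``cls``; symmetric in P and G."""
    p = np.asarray(pred_labels) == cls
    g = np.asarray(gt) == cls
    np_, ng = int(p.sum()), int(g.sum())
    if np_ == 0 and ng == 0:
        return 1.0
    return 2.0 * int((p & g).sum()) / (np_ + ng)


def _boundary(mask: np.ndarray) -> np.ndarray:
    """Coordinates of boundary pixels (mask minus its erosion)."""
    if not mask.any():
        return np.empty((0, 2))
    er = ndimage.binary_erosion(mask, border_value=0)
    return np.argwhere(mask & ~er)


def hausdorff(pred_labels: np.ndarray, gt: np.ndarray,
              cls: int) -> tuple[float, bool]:
    """Symmetric boundary Hausdorff distance in pixels.

    Returns ``(distance, degenerate)``; ``degenerate`` marks the
    one-side-empty convention (distance = image diagonal).
    """
    p = np.asarray(pred_labels) == cls
    g = np.asarray(gt) == cls
    if not p.any() and not g.any():
        return 0.0, False
    if p.any() != g.any():
        h, w = p.shape
        return float(np.hypot(h, w)), True
    bp, bg = _boundary(p), _boundary(g)
    d = max(directed_hausdorff(bp, bg)[0], directed_hausdorff(bg, bp)[0])
    return float(d), False


@dataclass(frozen=True)
class ProbMetrics:
    sensitivity: float
    specificity: float
    auc: float
    aupr: float


def prob_metrics(pred_probs: np.ndarray, gt: np.ndarray,
                 cls: int) -> ProbMetrics:
    """Sensitivity/specificity at the argmax label plus AUC/AUPR from the
    class-probability channel."""
    probs = np.asarray(pred_probs)
    gt = np.asarray(gt)
    labels = np.argmax(probs, axis=0)
    pos = (gt == cls).ravel()
    pred_pos = (labels == cls).ravel()
    score = probs[cls].ravel()

    tp = int((pred_pos & pos).sum())
    fn = int((~pred_pos & pos).sum())
    tn = int((~pred_pos & ~pos).sum())
    fp = int((pred_pos & ~pos).sum())

    if pos.sum() == 0:
        return ProbMetrics(np.nan, tn / (tn + fp) if tn + fp else np.nan,
                           np.nan, np.nan)
    sens = tp / (tp + fn)
    spec = tn / (tn + fp) if (tn + fp) else np.nan
    if pos.all():
        auc = aupr = np.nan
    else:
        auc = float(roc_auc_score(pos, score))
        aupr = float(average_precision_score(pos, score))
    return ProbMetrics(sens, spec, auc, aupr)


@dataclass(frozen=True)
class PairedComparison:
    t: float
    p: float
    stars: str
    degenerate: bool


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare_paired(scores_a, scores_b) -> PairedComparison:
    """Two-sided paired t-test on per-sample score differences."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length score lists of length >= 2")
    d = a - b
    if np.allclose(d, 0.0):
        return PairedComparison(0.0, 1.0, "ns", False)
    if np.isclose(d.std(ddof=1), 0.0):
        # constant nonzero difference: the t statistic diverges
        return PairedComparison(np.inf if d.mean() > 0 else -np.inf,
                                0.0, "***", True)
    t, p = sstats.ttest_rel(a, b)
    return PairedComparison(float(t), float(p), _stars(float(p)), False)


def evaluate_samples(model, samples, n_classes: int) -> pd.DataFrame:
    """Per-image, per-foreground-class metric table for a fitted model."""
    if not samples:
        raise ValueError("empty evaluation set")
    rows = []
    for s in samples:
        probs = model.predict_probs(s.image)[0]
        labels = np.argmax(probs, axis=0)
        for cls in range(1, n_classes + 1):
            hd, degen = hausdorff(labels, s.mask, cls)
            pm = prob_metrics(probs, s.mask, cls)
            rows.append(dict(image_id=s.id, cls=cls,
                             dice=dice(labels, s.mask, cls), hd=hd,
                             hd_degenerate=degen, sens=pm.sensitivity,
                             spec=pm.specificity, auc=pm.auc, aupr=pm.aupr))
    return pd.DataFrame(rows)


def evaluate_model(model, manifest) -> pd.DataFrame:
    if len(manifest) == 0:
        raise ValueError("empty manifest")
    return evaluate_samples(model, manifest.load_all(), manifest.n_classes)


def summarize(table: pd.DataFrame) -> dict:
    """Per-class and overall means; NaN (undefined) entries are excluded."""
    out: dict = {"per_class": {}, "mean": {}}
    metrics = ["dice", "hd", "sens", "spec", "auc", "aupr"]
    for cls, sub in table.groupby("cls"):
        out["per_class"][int(cls)] = {m: float(np.nanmean(sub[m]))
                                      for m in metrics}
    for m in metrics:
        out["mean"][m] = float(np.nanmean(table[m]))
    return out
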