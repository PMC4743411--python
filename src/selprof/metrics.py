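"""Classification metrics with the conventions the evaluation harness needs.

Implemented from their defining formulas (rather than delegated) because the
macro-averaging-over-labels-with-missing-annotations harness is the point of
the package; scikit-learn serves as the independent cross-check in the test
suite.  Conventions: an MCC whose denominator vanishes is 0; AUC is the
Mann-Whitney rank statistic with tie correction; multi-class AUC is the
unweighted one-vs-rest mean; macro averages are plain arithmetic means.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np


def confusion_counts(truths, predictions) -> tuple[int, int, int, int]:
    """(tp, tn, fp, fn) for binary truths/predictions."""
    t = np.asarray(truths, dtype=int)
    p = np.asarray(predictions, dtype=int)
    if t.size == 0:
        raise ValueError("empty input")
    tp = int(((t == 1) & (p == 1)).sum())
    tn = int(((t == 0) & (p == 0)).sum())
    fp = int(((t == 0) & (p == 1)).sum())
    fn = int(((t == 1) & (p == 0)).sum())
    return tp, tn, fp, fn


def accuracy(tp: int, tn: int, fp: int, fn: int) -> float:
    total = tp + tn + fp + fn
    if total == 0:
        raise ValueError("empty confusion counts")
    return (tp + tn) / total


def mcc(tp: int, tn: int, fp: int, fn: int) -> float:
    """Matthews correlation coefficient; 0 when the denominator vanishes."""
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("negative confusion counts")
    if tp + tn + fp + fn == 0:
        raise ValueError("empty confusion counts")
    denom = math.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / denom


def cohen_kappa(confusion) -> float:
    """Chance-corrected agreement from a square confusion matrix
    (rows: truth, columns: prediction)."""
    c = np.asarray(confusion, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError("confusion matrix must be square")
    n = c.sum()
    if n == 0:
        raise ValueError("empty confusion matrix")
    po = np.trace(c) / n
    pe = float((c.sum(axis=0) * c.sum(axis=1)).sum()) / (n * n)
    if pe == 1.0:
        return 0.0
    return (po - pe) / (1.0 - pe)


def auc(scores, truths) -> float:
    """Area under the ROC curve as the tie-corrected rank statistic.

    Equals P(score_pos > score_neg) + 0.5 P(tie) over positive/negative
    pairs.  Raises when only one class is present.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(truths, dtype=int)
    if s.size == 0:
        raise ValueError("empty input")
    pos = s[t == 1]
    neg = s[t == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("AUC undefined with a single class")
    order = np.argsort(np.concatenate([pos, neg]), kind="mergesort")
    ranks = np.empty(order.size, dtype=float)
    sorted_vals = np.concatenate([pos, neg])[order]
    # mid-ranks for ties
    i = 0
    while i < sorted_vals.size:
        j = i
        while j + 1 < sorted_vals.size and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i:j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    r_pos = ranks[: pos.size].sum()
    return (r_pos - pos.size * (pos.size + 1) / 2.0) / (pos.size * neg.size)


def multiclass_auc(score_matrix, truths) -> float:
    """Unweighted one-vs-rest mean AUC over the classes present in truth."""
    s = np.asarray(score_matrix, dtype=float)
    t = np.asarray(truths, dtype=int)
    aucs = []
    for k in sorted(set(t.tolist())):
        binary = (t == k).astype(int)
        if binary.sum() in (0, binary.size):
            continue
        aucs.append(auc(s[:, k], binary))
    if not aucs:
        raise ValueError("no class with both positives and negatives")
    return float(np.mean(aucs))


def macro_average(per_label_values: Sequence[float]) -> float:
    """Arithmetic mean across labels (macro-averaging)."""
    vals = [v for v in per_label_values]
    if not vals:
        raise ValueError("no per-label values to average")
    return float(np.mean(vals))
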