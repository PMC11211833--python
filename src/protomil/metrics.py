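"""Binary evaluation metrics for bag-level prediction.

Implements the full suite used to benchmark weakly supervised HER2
status predictors: positive-class F1 (posF1), support-weighted precision
/ recall / F1 (wPRC, wREC, wF1), balanced accuracy (bACC = mean of
sensitivity and specificity), AUROC by rank statistics (tie-aware
Mann-Whitney) and AUPRC as average precision (step-wise integration of
the precision-recall curve at every unique score threshold). These are
written out explicitly so they can be validated against an independent
reference implementation rather than delegated to it.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

from .errors import DataError, ParameterError

__all__ = ["confusion", "binary_metrics", "auroc", "auprc", "METRIC_NAMES"]

METRIC_NAMES = ("posF1", "wPRC", "wREC", "wF1", "bACC", "auroc", "auprc")


def _check(labels, scores):
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=np.float64)
    if labels.shape != scores.shape or labels.ndim != 1:
        raise ParameterError("labels and scores must be 1-D and the same length")
    if not np.isfinite(scores).all():
        raise DataError("scores contain non-finite values")
    if not np.isin(labels, (0, 1)).all():
        raise DataError("labels must be 0/1")
    return labels.astype(np.int64), scores


def confusion(labels, preds) -> tuple[int, int, int, int]:
    """(TP, FP, TN, FN) at binary predictions."""
    labels = np.asarray(labels)
    preds = np.asarray(preds)
    tp = int(np.sum((preds == 1) & (labels == 1)))
    fp = int(np.sum((preds == 1) & (labels == 0)))
    tn = int(np.sum((preds == 0) & (labels == 0)))
    fn = int(np.sum((preds == 0) & (labels == 1)))
    return tp, fp, tn, fn


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return prec, rec, f1


def auroc(labels, scores) -> float:
    """Area under the ROC curve via tie-averaged ranks."""
    labels, scores = _check(labels, scores)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise DataError("AUROC undefined: only one class present")
    r = rankdata(scores)
    return float((r[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def auprc(labels, scores) -> float:
    """Average precision: sum over thresholds of (dRecall * Precision)."""
    labels, scores = _check(labels, scores)
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise DataError("AUPRC undefined: no positive labels")
    order = np.argsort(-scores, kind="mergesort")
    y = labels[order]
    s = scores[order]
    tp = np.cumsum(y)
    fp = np.cumsum(1 - y)
    # evaluate only at the last occurrence of each unique score
    last = np.r_[s[1:] != s[:-1], True]
    tp, fp = tp[last], fp[last]
    precision = tp / (tp + fp)
    recall = tp / n_pos
    drec = np.diff(np.r_[0.0, recall])
    return float(np.sum(drec * precision))


def binary_metrics(labels, scores, threshold: float = 0.5) -> dict[str, float]:
    """All metrics at once; class metrics threshold scores at 0.5.

    Raises :class:`DataError` for the rank metrics when only one class
    is present; class metrics are still well defined and can be obtained
    by calling the per-metric helpers.
    """
    labels, scores = _check(labels, scores)
    preds = (scores >= threshold).astype(np.int64)
    tp, fp, tn, fn = confusion(labels, preds)
    prec1, rec1, f1_pos = _prf(tp, fp, fn)
    prec0, rec0, f1_neg = _prf(tn, fn, fp)  # negative class: swap roles
    n = len(labels)
    sup1 = tp + fn
    sup0 = tn + fp
    w_prc = (sup1 * prec1 + sup0 * prec0) / n
    w_rec = (sup1 * rec1 + sup0 * rec0) / n
    w_f1 = (sup1 * f1_pos + sup0 * f1_neg) / n
    sens = rec1 if sup1 else 0.0
    spec = rec0 if sup0 else 0.0
    bacc = 0.5 * (sens + spec)
    return {
        "posF1": f1_pos,
        "wPRC": w_prc,
        "wREC": w_rec,
        "wF1": w_f1,
        "bACC": bacc,
        "auroc": auroc(labels, scores),
        "auprc": auprc(labels, scores),
    }
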