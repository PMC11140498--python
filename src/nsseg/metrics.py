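"""Examination- and pixel-level evaluation metrics.

Exam-level classification is scored with ROC AUC over exam scores.
Pixel-level localization is scored with the Dice similarity coefficient
(predictions binarized at a configurable threshold, pooled over all
images of a set) and with non-interpolated average precision over the
pooled per-pixel ranking.  An operating-point helper reports specificity
at a required sensitivity, and ``majority_vote`` fuses an odd number of
reader labels into a reference standard.
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = [
    "roc_auc",
    "dice",
    "pooled_dice",
    "pixel_average_precision",
    "specificity_at_sensitivity",
    "majority_vote",
]


def _check_binary(labels: np.ndarray) -> None:
    classes = np.unique(labels)
    if not np.isin(classes, (0, 1)).all():
        raise ValueError("labels must be binary")
    if classes.size < 2:
        name = "positive" if classes.size and classes[0] == 1 else "negative"
        raise ValueError(f"labels contain only the {name} class; AUC undefined")


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve (= Mann-Whitney P(score+ > score-) with
    ties counted half)."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    _check_binary(labels)
    return float(roc_auc_score(labels, scores))


def dice(pred_mask: np.ndarray, ref_mask: np.ndarray) -> float:
    """Dice similarity coefficient 2|A∩B|/(|A|+|B|); 1 when both empty."""
    pred = np.asarray(pred_mask).astype(bool)
    ref = np.asarray(ref_mask).astype(bool)
    if pred.shape != ref.shape:
        raise ValueError("mask shape mismatch")
    denom = pred.sum() + ref.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(pred, ref).sum() / denom)


def pooled_dice(prob_maps, ref_masks, threshold: float = 0.5) -> float:
    """One global Dice over the pooled pixels of a set of images.

    Probability maps are binarized at ``threshold``.  Pooling (rather
    than per-image averaging) makes the score of a bootstrap set a single
    overlap of all its predicted and reference pixels.
    """
    pred = np.concatenate([np.asarray(p).ravel() >= threshold for p in prob_maps])
    ref = np.concatenate([np.asarray(r).ravel().astype(bool) for r in ref_masks])
    return dice(pred, ref)


def pixel_average_precision(prob_maps, ref_masks) -> float:
    """Non-interpolated AP over the pooled per-pixel ranking.

    Pixels of all images are pooled, ranked by descending score, and AP is
    the mean of the precision values at each positive's rank.
    """
    scores = np.concatenate([np.asarray(p, dtype=np.float64).ravel() for p in prob_maps])
    labels = np.concatenate([np.asarray(r).ravel().astype(np.int8) for r in ref_masks])
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValueError("no positive pixels; AP undefined")
    order = np.argsort(-scores, kind="stable")
    ranked = labels[order]
    cum_tp = np.cumsum(ranked)
    precision = cum_tp / np.arange(1, ranked.size + 1)
    return float(precision[ranked == 1].sum() / n_pos)


def specificity_at_sensitivity(scores, labels, target_sens: float):
    """Highest threshold with sensitivity >= target; returns (threshold,
    specificity) there."""
    if not 0.0 < target_sens <= 1.0:
        raise ValueError("target sensitivity must be in (0, 1]")
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    _check_binary(labels)
    fpr, tpr, thresholds = roc_curve(labels, scores)
    ok = np.flatnonzero(tpr >= target_sens)
    i = ok[0]  # roc_curve thresholds are descending: first hit = highest
    return float(thresholds[i]), float(1.0 - fpr[i])


def majority_vote(reads) -> int:
    """Label held by more than half of an odd number of reads."""
    reads = np.asarray(reads)
    if reads.size % 2 == 0 or reads.size < 1:
        raise ValueError("majority vote requires an odd number of reads")
    if not np.isin(reads, (0, 1)).all():
        raise ValueError("reads must be binary")
    return int(reads.sum() * 2 > reads.size)
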