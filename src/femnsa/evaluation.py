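"""Evaluation metrics: Dice / mean IoU for segmentation agreement,
error and accuracy statistics for angle comparison, a two-sample
Student's t-test, and cross-entropy for probabilistic labels."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "SegScores",
    "ErrorStats",
    "confusion_counts",
    "dice_scores",
    "miou_score",
    "seg_scores",
    "angle_error_stats",
    "t_test_two_sample",
    "cross_entropy",
    "comparison_report",
]


@dataclass(frozen=True)
class SegScores:
    """Per-class and aggregate segmentation-agreement scores.

    Per class c: Dice = 2 TP / (2 TP + FP + FN) and
    IoU = TP / (TP + FP + FN).  Macro values are arithmetic means over
    the classes present in prediction or truth; a class absent from both
    scores 1 by convention and is excluded from the macro mean.  Micro
    values pool the confusion counts over classes first.
    """

    per_class_dice: dict[int, float]
    macro_dice: float
    per_class_iou: dict[int, float]
    miou: float
    micro_dice: float
    micro_iou: float
    excluded_classes: tuple[int, ...] = ()


@dataclass(frozen=True)
class ErrorStats:
    """Pairwise angle-comparison statistics.

    error_i = |ref_i - cand_i| (deg) and
    accuracy_i = (1 - |(ref_i - cand_i) / ref_i|) * 100 (%), with means
    over pairs; t_stat / p_value come from the two-sample t-test between
    the two angle lists.
    """

    per_pair_error: np.ndarray
    mean_error: float
    per_pair_accuracy: np.ndarray
    mean_accuracy: float
    t_stat: float
    p_value: float


def _check_labels(pred, truth, num_classes: int) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape or pred.ndim != 1:
        raise ValueError("pred and truth must be 1-D arrays of equal length")
    if pred.size == 0:
        raise ValueError("label arrays are empty")
    if num_classes < 1:
        raise ValueError("num_classes must be >= 1")
    for name, a in (("pred", pred), ("truth", truth)):
        if a.min() < 0 or a.max() >= num_classes:
            raise ValueError(f"{name} labels must lie in [0, {num_classes})")
    return pred.astype(np.int64), truth.astype(np.int64)


def confusion_counts(pred, truth, num_classes: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-class (TP, FP, FN) counts in one-vs-rest form."""
    pred, truth = _check_labels(pred, truth, num_classes)
    cm = np.bincount(truth * num_classes + pred, minlength=num_classes**2).reshape(
        num_classes, num_classes
    )
    tp = np.diag(cm).astype(float)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    return tp, fp, fn


def seg_scores(pred, truth, num_classes: int = 3) -> SegScores:
    """Dice and IoU, per class and aggregated (macro and micro)."""
    tp, fp, fn = confusion_counts(pred, truth, num_classes)
    present = (tp + fp + fn) > 0
    dice = np.ones(num_classes)
    iou = np.ones(num_classes)
    np.divide(2 * tp, 2 * tp + fp + fn, out=dice, where=present)
    np.divide(tp, tp + fp + fn, out=iou, where=present)
    excluded = tuple(int(c) for c in np.nonzero(~present)[0])
    macro_dice = float(dice[present].mean()) if present.any() else 1.0
    miou = float(iou[present].mean()) if present.any() else 1.0
    micro_dice = float(2 * tp.sum() / (2 * tp.sum() + fp.sum() + fn.sum()))
    micro_iou = float(tp.sum() / (tp.sum() + fp.sum() + fn.sum()))
    return SegScores(
        per_class_dice={c: float(dice[c]) for c in range(num_classes)},
        macro_dice=macro_dice,
        per_class_iou={c: float(iou[c]) for c in range(num_classes)},
        miou=miou,
        micro_dice=micro_dice,
        micro_iou=micro_iou,
        excluded_classes=excluded,
    )


def dice_scores(pred, truth, num_classes: int = 3) -> SegScores:
    """Alias of :func:`seg_scores` emphasizing the Dice part."""
    return seg_scores(pred, truth, num_classes)


def miou_score(pred, truth, num_classes: int = 3) -> SegScores:
    """Alias of :func:`seg_scores` emphasizing the mean-IoU part."""
    return seg_scores(pred, truth, num_classes)


def t_test_two_sample(x, y) -> tuple[float, float]:
    """Pooled-variance two-sample Student's t-test, two-tailed.

    Degenerate zero-variance inputs: equal-mean constant samples give
    (t, p) = (0, 1); unequal-mean constant samples give an infinite t
    with p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if x.std(ddof=1) == 0.0 and y.std(ddof=1) == 0.0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        return math.copysign(math.inf, x.mean() - y.mean()), 0.0
    t, p = stats.ttest_ind(x, y, equal_var=True)
    return float(t), float(p)


def angle_error_stats(reference, candidate) -> ErrorStats:
    """Pairwise error/accuracy between two angle lists (degrees)."""
    ref = np.asarray(reference, dtype=float)
    cand = np.asarray(candidate, dtype=float)
    if ref.shape != cand.shape or ref.ndim != 1 or ref.size == 0:
        raise ValueError("reference and candidate must be equal-length nonempty 1-D arrays")
    if np.any(ref <= 0):
        raise ValueError("reference angles must be positive")
    err = np.abs(ref - cand)
    acc = (1.0 - np.abs((ref - cand) / ref)) * 100.0
    t, p = t_test_two_sample(ref, cand) if ref.size >= 2 else (0.0, 1.0)
    return ErrorStats(
        per_pair_error=err,
        mean_error=float(err.mean()),
        per_pair_accuracy=acc,
        mean_accuracy=float(acc.mean()),
        t_stat=t,
        p_value=p,
    )


def cross_entropy(probs, truth) -> float:
    """Mean negative log-probability of the true class.

    ``probs`` is (N, M) with rows summing to 1 (+- 1e-9); probabilities
    are clipped below at 1e-12 before the log.
    """
    p = np.asarray(probs, dtype=float)
    t = np.asarray(truth)
    if p.ndim != 2 or t.shape != (p.shape[0],):
        raise ValueError("probs must be (N, M) with one truth label per row")
    if np.any(np.abs(p.sum(axis=1) - 1.0) > 1e-9) or np.any(p < -1e-12):
        raise ValueError("each probability row must be nonnegative and sum to 1")
    if t.min() < 0 or t.max() >= p.shape[1]:
        raise ValueError("truth labels out of range")
    picked = np.clip(p[np.arange(len(t)), t.astype(int)], 1e-12, None)
    return float(-np.mean(np.log(picked)))


def comparison_report(reference, candidate, ref_name="reference", cand_name="candidate") -> dict:
    """Cohort-style comparison of two angle columns.

    Returns mean +- SD and min-max per column, the mean error and mean
    accuracy of the pairing, and the two-sample t statistic and p-value.
    """
    ref = np.asarray(reference, dtype=float)
    cand = np.asarray(candidate, dtype=float)
    es = angle_error_stats(ref, cand)

    def col(a):
        return {
            "mean": float(a.mean()),
            "sd": float(a.std(ddof=1)) if a.size > 1 else 0.0,
            "min": float(a.min()),
            "max": float(a.max()),
        }

    return {
        "n": int(ref.size),
        ref_name: col(ref),
        cand_name: col(cand),
        "error": {
            "mean": es.mean_error,
            "sd": float(es.per_pair_error.std(ddof=1)) if ref.size > 1 else 0.0,
            "min": float(es.per_pair_error.min()),
            "max": float(es.per_pair_error.max()),
        },
        "mean_accuracy_pct": es.mean_accuracy,
        "t_stat": es.t_stat,
        "p_value": es.p_value,
    }
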