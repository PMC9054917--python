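"""Multi-label evaluation metrics: average precision, micro-F1, macro-F1.

Average precision is ranking-based: for each instance the labels are
ordered by descending decision score, and for every relevant (truly
positive) label one measures the fraction of relevant labels at or above
its rank; the metric averages these fractions over relevant labels and
then over instances.  Micro-F1 pools true/false positives and false
negatives across labels before forming F1; macro-F1 averages per-label F1
values.  All three lie in [0, 1], larger is better.

Conventions (stated here because they matter for edge cases):

* score ties in the ranking break toward the smaller label index;
* instances with no relevant label are skipped by average precision and
  counted in ``n_skipped``;
* an F1 ratio with zero denominator is defined as 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidInputError, UndefinedMetricError

__all__ = [
    "ConfusionCounts",
    "MetricResult",
    "average_precision",
    "confusion_counts",
    "f1_micro",
    "f1_macro",
    "compute_all",
]


@dataclass(frozen=True)
class MetricResult:
    name: str
    value: float
    n_evaluated: int
    n_skipped: int = 0


@dataclass(frozen=True)
class ConfusionCounts:
    """Per-label confusion counts; arrays of length L."""

    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray

    @property
    def n_labels(self) -> int:
        return self.tp.size

    @property
    def n_instances(self) -> int:
        return int(self.tp[0] + self.fp[0] + self.fn[0] + self.tn[0]) if self.n_labels else 0


def _check_pm1(A: np.ndarray, name: str) -> np.ndarray:
    A = np.asarray(A)
    if not np.isin(A, (-1, 1)).all():
        raise InvalidInputError(f"{name} entries must be in {{-1, +1}}")
    return A


def average_precision(scores: np.ndarray, Y_true: np.ndarray) -> MetricResult:
    """Ranking-based average precision over instances with >= 1 relevant label."""
    scores = np.asarray(scores, dtype=float)
    Y_true = _check_pm1(Y_true, "Y_true")
    if scores.shape != Y_true.shape:
        raise InvalidInputError("scores and Y_true must have the same shape")
    n, L = scores.shape
    vals = []
    n_skipped = 0
    label_idx = np.arange(L)
    for i in range(n):
        relevant = Y_true[i] == 1
        if not relevant.any():
            n_skipped += 1
            continue
        # descending score; ties -> smaller label index first
        order = np.lexsort((label_idx, -scores[i]))
        rank = np.empty(L, dtype=int)
        rank[order] = np.arange(1, L + 1)
        rel_ranks = np.sort(rank[relevant])
        # among labels ranked at or above each relevant label, how many are relevant
        fracs = np.arange(1, rel_ranks.size + 1) / rel_ranks
        vals.append(fracs.mean())
    if not vals:
        raise UndefinedMetricError("average precision undefined: no instance has a relevant label")
    return MetricResult("avgprec", float(np.mean(vals)), n_evaluated=len(vals), n_skipped=n_skipped)


def confusion_counts(Y_pred: np.ndarray, Y_true: np.ndarray) -> ConfusionCounts:
    """Per-label confusion counts for predictions and truth in {-1, +1}."""
    Y_pred = _check_pm1(Y_pred, "Y_pred")
    Y_true = _check_pm1(Y_true, "Y_true")
    if Y_pred.shape != Y_true.shape:
        raise InvalidInputError("Y_pred and Y_true must have the same shape")
    pos_p, pos_t = Y_pred == 1, Y_true == 1
    return ConfusionCounts(
        tp=np.sum(pos_p & pos_t, axis=0),
        fp=np.sum(pos_p & ~pos_t, axis=0),
        fn=np.sum(~pos_p & pos_t, axis=0),
        tn=np.sum(~pos_p & ~pos_t, axis=0),
    )


def _f1(tp: float, fp: float, fn: float) -> float:
    denom = 2.0 * tp + fp + fn
    return float(2.0 * tp / denom) if denom > 0 else 0.0


def f1_micro(counts: ConfusionCounts) -> MetricResult:
    """F1 of the label-pooled counts."""
    value = _f1(counts.tp.sum(), counts.fp.sum(), counts.fn.sum())
    return MetricResult("micro_f1", value, n_evaluated=counts.n_instances)


def f1_macro(counts: ConfusionCounts) -> MetricResult:
    """Mean of per-label F1 values; labels with empty denominators contribute 0."""
    per_label = [_f1(t, p, f) for t, p, f in zip(counts.tp, counts.fp, counts.fn)]
    degenerate = int(np.sum((counts.tp + counts.fp + counts.fn) == 0))
    return MetricResult(
        "macro_f1",
        float(np.mean(per_label)),
        n_evaluated=counts.n_instances,
        n_skipped=degenerate,
    )


def compute_all(scores: np.ndarray, Y_pred: np.ndarray, Y_true: np.ndarray) -> dict[str, float]:
    """The three headline metrics as a flat dict."""
    counts = confusion_counts(Y_pred, Y_true)
    return {
        "avgprec": average_precision(scores, Y_true).value,
        "micro_f1": f1_micro(counts).value,
        "macro_f1": f1_macro(counts).value,
    }
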