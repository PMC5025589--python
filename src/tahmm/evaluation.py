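"""Confusion-count metrics, ROC curves and AUC.

Metrics follow the standard definitions

    Accuracy    = (TP + TN) / (TP + FP + FN + TN)
    Sensitivity = TP / (TP + FN)
    Specificity = TN / (FP + TN)
    BER         = (FN / (TP + FN) + FP / (FP + TN)) / 2

AUC is computed as the Mann-Whitney probability that a random positive
outscores a random negative, with ties counted 1/2, via rank statistics;
it equals the trapezoidal area under the stepwise ROC curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @classmethod
    def from_verdicts(cls, y_true, y_pred) -> "ConfusionCounts":
        """Counts from boolean truth / prediction vectors."""
        t = np.asarray(y_true, dtype=bool)
        p = np.asarray(y_pred, dtype=bool)
        if t.shape != p.shape:
            raise ValueError("y_true and y_pred must have equal length")
        return cls(
            tp=int(np.count_nonzero(t & p)),
            fp=int(np.count_nonzero(~t & p)),
            fn=int(np.count_nonzero(t & ~p)),
            tn=int(np.count_nonzero(~t & ~p)),
        )


@dataclass(frozen=True)
class MetricSet:
    accuracy: float
    sensitivity: float
    specificity: float
    ber: float


def metrics(counts: ConfusionCounts) -> MetricSet:
    """Accuracy, sensitivity, specificity and BER for a confusion table."""
    n_pos = counts.tp + counts.fn
    n_neg = counts.fp + counts.tn
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            "metrics undefined: need at least one positive and one negative"
        )
    total = n_pos + n_neg
    return MetricSet(
        accuracy=(counts.tp + counts.tn) / total,
        sensitivity=counts.tp / n_pos,
        specificity=counts.tn / n_neg,
        ber=(counts.fn / n_pos + counts.fp / n_neg) / 2.0,
    )


def roc_auc(scores_pos, scores_neg) -> tuple[np.ndarray, float]:
    """ROC curve points and the rank-based (Mann-Whitney) AUC.

    Returns ``(points, auc)`` where ``points`` is an array of
    ``(1 - specificity, sensitivity)`` pairs over all distinct thresholds
    (classification: score >= threshold), from (0, 0) to (1, 1).
    """
    pos = np.asarray(list(scores_pos), dtype=float)
    neg = np.asarray(list(scores_neg), dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score lists must be non-empty")
    pooled = np.concatenate([pos, neg])
    ranks = rankdata(pooled)  # average ranks handle ties with the 1/2 rule
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    auc = float(u / (pos.size * neg.size))
    thresholds = np.unique(pooled)[::-1]
    points = [(0.0, 0.0)]
    for thr in thresholds:
        tpr = float(np.count_nonzero(pos >= thr)) / pos.size
        fpr = float(np.count_nonzero(neg >= thr)) / neg.size
        points.append((fpr, tpr))
    points.append((1.0, 1.0))
    return np.array(points), auc


def report_table(rows: dict[str, ConfusionCounts]) -> str:
    """Plain-text evaluation table: one row per negative set plus a
    pooled row when several sets are given (sensitivity, specificity and
    raw counts, 3-decimal round-half-even)."""
    lines = [
        f"{'Negative data':<14}{'Sens':>7}{'Spec':>7}"
        f"{'TP':>6}{'FP':>6}{'FN':>6}{'TN':>7}"
    ]

    def fmt(name: str, c: ConfusionCounts) -> str:
        m = metrics(c)
        return (
            f"{name:<14}{m.sensitivity:>7.3f}{m.specificity:>7.3f}"
            f"{c.tp:>6d}{c.fp:>6d}{c.fn:>6d}{c.tn:>7d}"
        )

    for name, counts in rows.items():
        lines.append(fmt(name, counts))
    return "\n".join(lines)
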