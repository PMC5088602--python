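"""Evaluation metrics for benchmarking predictions against ground truth.

Balanced accuracy = (sensitivity + specificity) / 2, with
sensitivity = TP / (TP + FN) over truly present items and
specificity = TN / (TN + FP) over truly absent items;
FDR = FP / (TP + FP) over called items.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class MetricsReport:
    """Confusion-matrix metrics with their underlying counts."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")

    @property
    def balanced_accuracy(self) -> float:
        return (self.sensitivity + self.specificity) / 2.0

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else float("nan")

    @property
    def fdr(self) -> float:
        return self.fp / (self.tp + self.fp) if self.tp + self.fp else float("nan")

    @property
    def f1(self) -> float:
        s, p = self.sensitivity, self.precision
        return 2 * s * p / (s + p) if (s + p) > 0 else 0.0


def classification_metrics(predicted: set, truth: set, universe: set) -> MetricsReport:
    """Score a predicted item set against truth within a finite universe."""
    if not universe:
        raise ValueError("empty universe")
    if not predicted <= universe or not truth <= universe:
        raise ValueError("predicted and truth sets must be subsets of the universe")
    tp = len(predicted & truth)
    fp = len(predicted - truth)
    fn = len(truth - predicted)
    tn = len(universe) - tp - fp - fn
    return MetricsReport(tp, fp, fn, tn)


def pair_f1(predicted_partition: dict[str, str], true_partition: dict[str, str]) -> MetricsReport:
    """Pairwise clustering agreement: every item pair is positive when
    co-clustered. Returns the confusion report (use .f1)."""
    items = sorted(true_partition)
    tp = fp = fn = tn = 0
    for i, a in enumerate(items):
        for b in items[i + 1 :]:
            same_pred = predicted_partition[a] == predicted_partition[b]
            same_true = true_partition[a] == true_partition[b]
            if same_pred and same_true:
                tp += 1
            elif same_pred:
                fp += 1
            elif same_true:
                fn += 1
            else:
                tn += 1
    return MetricsReport(tp, fp, fn, tn)


def r_squared(truth: np.ndarray, estimate: np.ndarray) -> float:
    """Squared Pearson correlation between truth and estimate."""
    truth = np.asarray(truth, dtype=float)
    estimate = np.asarray(estimate, dtype=float)
    if truth.shape != estimate.shape or truth.size < 2:
        raise ValueError("need two equal-length vectors of size >= 2")
    if np.allclose(truth, truth[0]) or np.allclose(estimate, estimate[0]):
        raise ValueError("r_squared undefined for a constant vector")
    r = np.corrcoef(truth, estimate)[0, 1]
    return float(r * r)
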