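"""Imbalance-aware evaluation: confusion matrices, per-class precision and
recall, microaveraged F1 (= accuracy for single-label multiclass), percentile
bootstrap confidence intervals, Cohen kappa and the prevalence-random
baseline."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .corpus import ClassDistribution, ClassLabel, LABELS

__all__ = [
    "ConfusionMatrix",
    "MetricReport",
    "confusion",
    "micro_f1",
    "expected_random_micro_f1",
    "bootstrap_ci",
    "cohen_kappa",
    "metric_report",
]

log = logging.getLogger(__name__)

_IDX = {lab: i for i, lab in enumerate(LABELS)}


def _coerce(labels: Sequence) -> list[ClassLabel]:
    return [l if isinstance(l, ClassLabel) else ClassLabel(str(l)) for l in labels]


@dataclass
class ConfusionMatrix:
    """4x4 counts; rows are true labels, columns predicted labels."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(LABELS), len(LABELS)):
            raise ValueError(f"expected {len(LABELS)}x{len(LABELS)} counts")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def tp(self, label: ClassLabel) -> int:
        i = _IDX[label]
        return int(self.counts[i, i])

    def fp(self, label: ClassLabel) -> int:
        i = _IDX[label]
        return int(self.counts[:, i].sum() - self.counts[i, i])

    def fn(self, label: ClassLabel) -> int:
        i = _IDX[label]
        return int(self.counts[i, :].sum() - self.counts[i, i])

    def precision(self, label: ClassLabel) -> tuple[float, bool]:
        """(precision, defined). Undefined (no predictions for the class)
        is reported as 0.0 with ``defined=False``."""
        tp, fp = self.tp(label), self.fp(label)
        if tp + fp == 0:
            return 0.0, False
        return tp / (tp + fp), True

    def recall(self, label: ClassLabel) -> tuple[float, bool]:
        tp, fn = self.tp(label), self.fn(label)
        if tp + fn == 0:
            return 0.0, False
        return tp / (tp + fn), True

    def error_share_into(self, true_label: ClassLabel, sink: ClassLabel) -> float:
        """Share of class ``true_label`` misclassifications landing in ``sink``."""
        i = _IDX[true_label]
        errors = self.counts[i, :].sum() - self.counts[i, i]
        if errors == 0:
            return 0.0
        return float(self.counts[i, _IDX[sink]]) / float(errors)


def confusion(y_true: Sequence, y_pred: Sequence) -> ConfusionMatrix:
    yt, yp = _coerce(y_true), _coerce(y_pred)
    if len(yt) != len(yp):
        raise ValueError(f"length mismatch: {len(yt)} true vs {len(yp)} predicted")
    if not yt:
        raise ValueError("cannot build a confusion matrix from zero items")
    counts = np.zeros((len(LABELS), len(LABELS)), dtype=np.int64)
    for t, p in zip(yt, yp):
        counts[_IDX[t], _IDX[p]] += 1
    return ConfusionMatrix(counts)


def micro_f1(cm: ConfusionMatrix) -> float:
    """Microaveraged F1: tp/fp/fn pooled over classes before the harmonic
    mean.  For single-label multiclass this equals accuracy (trace/total)."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    tp = sum(cm.tp(lab) for lab in LABELS)
    fp = sum(cm.fp(lab) for lab in LABELS)
    fn = sum(cm.fn(lab) for lab in LABELS)
    p = tp / (tp + fp)
    r = tp / (tp + fn)
    if p + r == 0:
        return 0.0
    return 2 * p * r / (p + r)


def expected_random_micro_f1(dist: ClassDistribution, uniform: bool = False) -> float:
    """Expected accuracy of a random classifier.

    Default: prevalence-proportional assignment (label c with probability
    p_c), giving sum of squared prevalences.  ``uniform=True`` instead
    assigns the 4 labels equiprobably, giving 1/len(classes).
    """
    if uniform:
        return 1.0 / len(LABELS)
    return float(sum(p * p for p in dist.proportions.values()))


def bootstrap_ci(
    y_true: Sequence,
    y_pred: Sequence,
    metric: Optional[Callable] = None,
    n_resamples: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap interval for ``metric(y_true*, y_pred*)`` over
    resamples of item indices drawn with replacement."""
    yt, yp = _coerce(y_true), _coerce(y_pred)
    if len(yt) != len(yp):
        raise ValueError("length mismatch")
    if len(yt) < 2:
        raise ValueError("need at least 2 items to bootstrap")
    if n_resamples < 100:
        log.warning("n_resamples=%d is low; intervals will be unstable", n_resamples)
    if metric is None:
        metric = lambda t, p: micro_f1(confusion(t, p))
    rng = np.random.default_rng(seed)
    yt_arr = np.asarray([l.value for l in yt], dtype=object)
    yp_arr = np.asarray([l.value for l in yp], dtype=object)
    n = len(yt)
    stats = np.empty(n_resamples)
    for b in range(n_resamples):
        idx = rng.integers(0, n, size=n)
        stats[b] = metric(yt_arr[idx], yp_arr[idx])
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(stats, [100 * alpha, 100 * (1 - alpha)])
    return float(lo), float(hi)


def cohen_kappa(labels_1: Sequence, labels_2: Sequence) -> float:
    """Chance-corrected agreement: (p_o - p_e) / (1 - p_e), with expected
    agreement from the two raters' marginals.  Defined as 1.0 when both
    raters are constant and identical (p_e = 1)."""
    l1, l2 = _coerce(labels_1), _coerce(labels_2)
    if len(l1) != len(l2):
        raise ValueError("length mismatch")
    if len(l1) < 2:
        raise ValueError("need at least 2 items")
    n = len(l1)
    p_o = sum(a == b for a, b in zip(l1, l2)) / n
    p_e = sum(
        (sum(a == lab for a in l1) / n) * (sum(b == lab for b in l2) / n)
        for lab in LABELS
    )
    if p_e >= 1.0 - 1e-12:
        return 1.0
    return (p_o - p_e) / (1.0 - p_e)


@dataclass
class MetricReport:
    """Table-style report: per-class precision/recall and micro-F1 with CI."""

    precision: dict[ClassLabel, float]
    recall: dict[ClassLabel, float]
    micro_f1: float
    ci_low: float
    ci_high: float
    undefined_precision: set[ClassLabel] = field(default_factory=set)
    undefined_recall: set[ClassLabel] = field(default_factory=set)

    def as_row(self, system: str) -> dict:
        row = {"system": system}
        for lab in LABELS:
            row[f"precision_{lab.value}"] = round(self.precision[lab], 3)
        for lab in LABELS:
            row[f"recall_{lab.value}"] = round(self.recall[lab], 3)
        row["micro_f1"] = round(self.micro_f1, 3)
        row["ci_low"] = round(self.ci_low, 3)
        row["ci_high"] = round(self.ci_high, 3)
        return row


def metric_report(
    y_true: Sequence,
    y_pred: Sequence,
    n_resamples: int = 1000,
    seed: int = 0,
) -> MetricReport:
    cm = confusion(y_true, y_pred)
    precision, recall = {}, {}
    undef_p, undef_r = set(), set()
    for lab in LABELS:
        precision[lab], ok = cm.precision(lab)
        if not ok:
            undef_p.add(lab)
        recall[lab], ok = cm.recall(lab)
        if not ok:
            undef_r.add(lab)
    f1 = micro_f1(cm)
    lo, hi = bootstrap_ci(y_true, y_pred, n_resamples=n_resamples, seed=seed)
    return MetricReport(precision, recall, f1, lo, hi, undef_p, undef_r)
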