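"""Classification metrics and the stratified k-fold cross-validation driver.

Binary metrics follow the textbook confusion-count formulas; ratios with
a zero denominator are reported as *absent* (None) and flagged, never
silently coerced to 0. AUC uses the rank (Mann-Whitney) formulation,
which equals the trapezoidal ROC area and handles score ties by midrank.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Callable, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import f1_score
from sklearn.model_selection import StratifiedKFold


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_predictions(cls, labels, predictions) -> "ConfusionCounts":
        y = np.asarray(labels).astype(int)
        p = np.asarray(predictions).astype(int)
        return cls(
            tp=int(((y == 1) & (p == 1)).sum()),
            fp=int(((y == 0) & (p == 1)).sum()),
            tn=int(((y == 0) & (p == 0)).sum()),
            fn=int(((y == 1) & (p == 0)).sum()),
        )


@dataclass
class MetricReport:
    precision: float | None = None
    accuracy: float | None = None
    specificity: float | None = None
    recall: float | None = None
    auc_roc: float | None = None
    micro_f1: float | None = None
    macro_f1: float | None = None
    undefined: list[str] = field(default_factory=list)
    folds: list[dict] = field(default_factory=list)
    mean: dict = field(default_factory=dict)
    sd: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("metric\tvalue\n")
            for k in ("precision", "accuracy", "specificity", "recall",
                      "auc_roc", "micro_f1", "macro_f1"):
                v = getattr(self, k)
                if v is not None:
                    fh.write(f"{k}\t{v!r}\n")


def binary_metrics(c: ConfusionCounts) -> MetricReport:
    """Precision/ACC/SPC/Recall from confusion counts."""
    if c.n < 1:
        raise ValueError("empty confusion table")
    report = MetricReport()

    def ratio(num, den, name):
        if den == 0:
            report.undefined.append(name)
            return None
        return num / den

    report.precision = ratio(c.tp, c.tp + c.fp, "precision")
    report.accuracy = ratio(c.tp + c.tn, c.n, "accuracy")
    report.specificity = ratio(c.tn, c.tn + c.fp, "specificity")
    report.recall = ratio(c.tp, c.tp + c.fn, "recall")
    return report


def auc_roc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Area under the ROC curve via midranks (tie-aware)."""
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape or y.ndim != 1:
        raise ValueError("labels and scores must be equal-length 1-D sequences")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def f1_scores(labels: Sequence, predictions: Sequence, averaging: str = "micro") -> float:
    """Micro (global pooling) or macro (unweighted class mean) F1."""
    if averaging not in ("micro", "macro"):
        raise ValueError(f"averaging must be micro|macro, got {averaging!r}")
    labels = list(labels)
    predictions = list(predictions)
    if not labels or len(labels) != len(predictions):
        raise ValueError("labels and predictions must be equal-length, non-empty")
    return float(f1_score(labels, predictions, average=averaging, zero_division=0))


FoldFn = Callable[[list, list], dict]


def cross_validate(
    examples: list,
    labels: Sequence,
    fold_fn: FoldFn,
    k: int = 5,
    seed: int = 0,
) -> MetricReport:
    """Stratified k-fold driver.

    ``fold_fn(train_examples, test_examples) -> {metric: value}`` is called
    once per fold; per-fold dicts are collected and summarized as
    mean +/- sd per metric.
    """
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(examples) < k:
        raise ValueError("need at least k examples")
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} examples; stratified {k}-fold "
            "needs every class to have >= k"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    report = MetricReport()
    for train_idx, test_idx in skf.split(np.zeros(len(examples)), labels):
        fold = fold_fn([examples[i] for i in train_idx], [examples[i] for i in test_idx])
        report.folds.append(fold)
    keys = sorted({key for fold in report.folds for key in fold})
    for key in keys:
        vals = [fold[key] for fold in report.folds if fold.get(key) is not None]
        if vals:
            report.mean[key] = float(np.mean(vals))
            report.sd[key] = float(np.std(vals))
            if hasattr(report, key):
                setattr(report, key, report.mean[key])
    return report


def roc_points(labels: Sequence[int], scores: Sequence[float]) -> list[tuple[float, float]]:
    """(FPR, TPR) points over all score thresholds, for curve export."""
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    order = np.argsort(-s, kind="stable")
    y = y[order]
    s = s[order]
    n_pos = max(1, int((y == 1).sum()))
    n_neg = max(1, int((y == 0).sum()))
    pts = [(0.0, 0.0)]
    tp = fp = 0
    for i in range(len(y)):
        if y[i] == 1:
            tp += 1
        else:
            fp += 1
        if i + 1 == len(y) or s[i + 1] != s[i]:
            pts.append((fp / n_neg, tp / n_pos))
    return pts


def write_roc_csv(path, labels, scores) -> None:
    with open(path, "w") as fh:
        fh.write("fpr,tpr\n")
        for fpr, tpr in roc_points(labels, scores):
            fh.write(f"{fpr!r},{tpr!r}\n")
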