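"""Cross-validated evaluation with macro-averaged confusion-matrix metrics.

Five-fold stratified cross-validation of the full pipeline: per fold the
sensor-importance table is built from the training fold only, both folds
are de-noised with it, the time clustering is fitted on the training
fold, and every test instance is recognised by top-n similarity voting.

Metrics follow the one-vs-rest convention: per class,

    Accuracy  = (TP + TN) / (TP + FP + FN + TN)
    Precision = TP / (TP + FP)
    Recall    = TP / (TP + FN)
    F-Measure = 2·TP / (2·TP + FP + FN)

macro values are unweighted means over classes; zero-denominator ratios
are reported as 0 and flagged.  Confusion matrices are oriented rows =
predicted, columns = actual.  Overall (micro) accuracy, trace/total, is
reported alongside since published headline accuracies are often micro.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from duoact.casas_io import ActivityInstance
from duoact.clustering import kmeans, select_k
from duoact.features import DenoiseConfig, build_sia, denoise
from duoact.recognition import RecognitionConfig, recognize

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "metrics_from_confusion",
    "cross_validate",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Square count matrix; ``counts[i, j]`` = predicted labels[i], actual labels[j]."""

    labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1] or arr.shape[0] != len(self.labels):
            raise ValueError("counts must be square and match the label list")
        if (arr < 0).any():
            raise ValueError("confusion-matrix entries must be non-negative")

    @classmethod
    def from_pairs(
        cls, pairs: Sequence[tuple[str, str]], labels: Sequence[str] | None = None
    ) -> "ConfusionMatrix":
        """Build from (predicted, actual) label pairs."""
        if labels is None:
            labels = sorted({lb for pair in pairs for lb in pair})
        idx = {lb: i for i, lb in enumerate(labels)}
        counts = np.zeros((len(labels), len(labels)), dtype=int)
        for pred, actual in pairs:
            counts[idx[pred], idx[actual]] += 1
        return cls(labels=tuple(labels), counts=counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if self.labels != other.labels:
            raise ValueError("cannot pool confusion matrices with different label lists")
        return ConfusionMatrix(self.labels, self.counts + other.counts)

    def to_frame(self) -> pd.DataFrame:
        """Rows = predicted, columns = actual."""
        return pd.DataFrame(self.counts, index=list(self.labels), columns=list(self.labels))


@dataclass(frozen=True)
class MetricsReport:
    """Per-class and macro metrics derived from a confusion matrix.

    ``per_class`` maps label -> {accuracy, precision, recall, f_measure};
    macro values are unweighted means over classes; ``micro_accuracy`` is
    trace/total.  ``degenerate`` lists (label, metric) pairs whose
    denominator was zero (reported as 0).
    """

    confusion: ConfusionMatrix
    per_class: dict[str, dict[str, float]]
    macro_accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f_measure: float
    micro_accuracy: float
    degenerate: tuple[tuple[str, str], ...] = ()
    fold_reports: tuple["MetricsReport", ...] = ()
    fold_assignment: tuple[int, ...] = ()
    seed: int | None = None

    def summary(self) -> dict[str, float]:
        return {
            "macro_accuracy": self.macro_accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f_measure": self.macro_f_measure,
            "micro_accuracy": self.micro_accuracy,
        }

    def to_json(self, **kwargs) -> str:
        payload = {
            **self.summary(),
            "per_class": self.per_class,
            "labels": list(self.confusion.labels),
            "confusion_rows_predicted": self.confusion.counts.tolist(),
            "degenerate": [list(pair) for pair in self.degenerate],
            "seed": self.seed,
            "n_instances": self.confusion.total,
        }
        if self.fold_reports:
            payload["per_fold"] = [r.summary() for r in self.fold_reports]
        kwargs.setdefault("indent", 2)
        return json.dumps(payload, **kwargs)


def metrics_from_confusion(cm: ConfusionMatrix) -> MetricsReport:
    """One-vs-rest accuracy/precision/recall/F per class, plus macro means.

    Raises
    ------
    ValueError
        If the matrix is empty (no counts).
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    counts = cm.counts.astype(float)
    total = counts.sum()
    per_class: dict[str, dict[str, float]] = {}
    degenerate: list[tuple[str, str]] = []

    def ratio(num: float, den: float, label: str, name: str) -> float:
        if den == 0:
            degenerate.append((label, name))
            return 0.0
        return num / den

    for i, label in enumerate(cm.labels):
        tp = counts[i, i]
        fp = counts[i, :].sum() - tp  # predicted i, actually other
        fn = counts[:, i].sum() - tp  # actually i, predicted other
        tn = total - tp - fp - fn
        per_class[label] = {
            "accuracy": ratio(tp + tn, total, label, "accuracy"),
            "precision": ratio(tp, tp + fp, label, "precision"),
            "recall": ratio(tp, tp + fn, label, "recall"),
            "f_measure": ratio(2 * tp, 2 * tp + fp + fn, label, "f_measure"),
        }

    def macro(name: str) -> float:
        return float(np.mean([m[name] for m in per_class.values()]))

    return MetricsReport(
        confusion=cm,
        per_class=per_class,
        macro_accuracy=macro("accuracy"),
        macro_precision=macro("precision"),
        macro_recall=macro("recall"),
        macro_f_measure=macro("f_measure"),
        micro_accuracy=float(np.trace(counts) / total),
        degenerate=tuple(degenerate),
    )


def _stratified_folds(
    labels: Sequence[str], folds: int, rng: np.random.Generator
) -> np.ndarray:
    """Fold index per instance; classes spread as evenly as possible.

    A class with fewer than ``folds`` instances still lands in some
    folds; a single-instance class is pinned to fold -1 (training only).
    """
    labels = np.asarray(labels)
    assignment = np.full(len(labels), -1, dtype=int)
    start = 0
    for lb in sorted(set(labels.tolist())):
        idx = np.flatnonzero(labels == lb)
        rng.shuffle(idx)
        if len(idx) == 1:
            warnings.warn(
                f"class {lb!r} has a single instance; kept in training only",
                stacklevel=3,
            )
            continue
        if len(idx) < folds:
            warnings.warn(
                f"class {lb!r} has {len(idx)} < {folds} instances; "
                "stratification degrades for it",
                stacklevel=3,
            )
        # rotate the starting fold across classes so small classes spread out
        for offset, i in enumerate(idx):
            assignment[i] = (start + offset) % folds
        start += len(idx)
    return assignment


def _evaluate_fold(
    train: list[ActivityInstance],
    test: list[ActivityInstance],
    denoise_cfg: DenoiseConfig,
    rec_cfg: RecognitionConfig,
    k: int | None,
    seed: int,
) -> list[tuple[str, str]]:
    """(predicted, actual) pairs for one fold; SIA/clustering from train only."""
    sia = build_sia([a.sq for a in train])
    train_dn = [denoise(a, sia, denoise_cfg) for a in train]
    test_dn = [denoise(a, sia, denoise_cfg) for a in test]

    points = [(float(a.bt), float(a.et)) for a in train_dn]
    n_classes = len({a.label for a in train_dn})
    if k is None:
        k_used = select_k(points, n_classes, seed=seed) if n_classes >= 3 else 1
    else:
        k_used = k
    k_used = min(k_used, len(np.unique(np.asarray(points), axis=0)))
    model = kmeans(points, k_used, seed=seed)
    indexed = list(zip(train_dn, model.assignment.tolist()))
    return [(recognize(indexed, model, t, rec_cfg), t.label) for t in test_dn]


def cross_validate(
    activities: Sequence[ActivityInstance],
    denoise_cfg: DenoiseConfig | None = None,
    rec_cfg: RecognitionConfig | None = None,
    folds: int = 5,
    seed: int = 0,
    k: int | None = None,
) -> MetricsReport:
    """Stratified k-fold cross-validation of the full recognition pipeline.

    Per fold: the SIA is rebuilt from the training fold only (no label
    leakage), both folds are de-noised with it, k-means is fitted on the
    training fold's (bt, et) points (k chosen by the elbow method unless
    given), and each test instance is recognised.  The returned report
    pools the fold confusion matrices; its macro metrics are the means of
    the per-fold macro metrics, and per-fold reports are attached.

    Reproducible: identical (activities, config, seed) give an identical
    report.
    """
    if denoise_cfg is None:
        denoise_cfg = DenoiseConfig()
    if rec_cfg is None:
        rec_cfg = RecognitionConfig()
    activities = list(activities)
    labels_all = sorted({a.label for a in activities})
    rng = np.random.default_rng(seed)
    fold_of = _stratified_folds([a.label for a in activities], folds, rng)

    fold_reports: list[MetricsReport] = []
    pooled: ConfusionMatrix | None = None
    for f in range(folds):
        train = [a for a, g in zip(activities, fold_of) if g != f]
        test = [a for a, g in zip(activities, fold_of) if g == f]
        if not test:
            warnings.warn(f"fold {f} is empty; skipped", stacklevel=2)
            continue
        pairs = _evaluate_fold(train, test, denoise_cfg, rec_cfg, k, seed)
        cm = ConfusionMatrix.from_pairs(pairs, labels=labels_all)
        fold_reports.append(metrics_from_confusion(cm))
        pooled = cm if pooled is None else pooled + cm

    if pooled is None:
        raise ValueError("no fold produced any test instance")

    def fold_mean(name: str) -> float:
        return float(np.mean([getattr(r, name) for r in fold_reports]))

    pooled_report = metrics_from_confusion(pooled)
    return MetricsReport(
        confusion=pooled,
        per_class=pooled_report.per_class,
        macro_accuracy=fold_mean("macro_accuracy"),
        macro_precision=fold_mean("macro_precision"),
        macro_recall=fold_mean("macro_recall"),
        macro_f_measure=fold_mean("macro_f_measure"),
        micro_accuracy=fold_mean("micro_accuracy"),
        degenerate=pooled_report.degenerate,
        fold_reports=tuple(fold_reports),
        fold_assignment=tuple(int(g) for g in fold_of),
        seed=seed,
    )
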