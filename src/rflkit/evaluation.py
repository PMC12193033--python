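"""Metric reports, confusion matrices, k-fold cross-validation.

Reports mirror the standard classification-report layout: one row per
exercise class with precision / recall / F1 / support, plus macro
(unweighted) and support-weighted averages and a K x K confusion
matrix.  Display values round half-up to 2 decimals; full precision is
retained internally and in machine-readable output.

``kfold_cv`` evaluates a classifier under stratified k-fold, optionally
recomputing transfer features inside each fold on that fold's training
part only, so no information crosses the fold boundary.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion_matrix
from sklearn.model_selection import StratifiedKFold

from .classifiers import ClassifierSpec, predict, train_classifier
from .dataio import EXERCISE_NAMES, FeatureTable
from .rfl import RFLConfig, RFLTransformer


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round half away from zero at the given precision (display rule)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def weighted_average(values, weights) -> float:
    """Support-weighted mean — the imbalance-aware table average."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    return float(np.sum(values * weights) / np.sum(weights))


def confusion_matrix(y_true, y_pred, n_classes: int) -> np.ndarray:
    """K x K counts; entry (i, j) = rows of true class i predicted as j."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    for name, arr in (("y_true", y_true), ("y_pred", y_pred)):
        if arr.size and (arr.min() < 0 or arr.max() >= n_classes):
            raise ValueError(f"{name} contains labels outside 0..{n_classes - 1}")
    return _sk_confusion_matrix(y_true, y_pred, labels=np.arange(n_classes))


@dataclass
class EvalReport:
    """Per-class and averaged classification metrics."""

    accuracy: float
    precision: np.ndarray        # (K,)
    recall: np.ndarray           # (K,)
    f1: np.ndarray               # (K,)
    support: np.ndarray          # (K,)
    confusion: np.ndarray        # (K, K)
    label_names: list[str]

    @property
    def macro_precision(self) -> float:
        return float(self.precision.mean())

    @property
    def macro_recall(self) -> float:
        return float(self.recall.mean())

    @property
    def macro_f1(self) -> float:
        return float(self.f1.mean())

    @property
    def weighted_precision(self) -> float:
        return weighted_average(self.precision, self.support)

    @property
    def weighted_recall(self) -> float:
        return weighted_average(self.recall, self.support)

    @property
    def weighted_f1(self) -> float:
        return weighted_average(self.f1, self.support)

    def to_frame(self, decimals: int = 2) -> pd.DataFrame:
        """Rendered table mirroring the per-class report layout."""
        rows = []
        for c, name in enumerate(self.label_names):
            rows.append({
                "Target exercise": name,
                "Precision": round_half_up(self.precision[c], decimals),
                "Recall": round_half_up(self.recall[c], decimals),
                "F1": round_half_up(self.f1[c], decimals),
                "Support": int(self.support[c]),
            })
        rows.append({
            "Target exercise": "Average",
            "Precision": round_half_up(self.weighted_precision, decimals),
            "Recall": round_half_up(self.weighted_recall, decimals),
            "F1": round_half_up(self.weighted_f1, decimals),
            "Support": int(self.support.sum()),
        })
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision.tolist(),
            "recall": self.recall.tolist(),
            "f1": self.f1.tolist(),
            "support": self.support.tolist(),
            "macro": {"precision": self.macro_precision,
                      "recall": self.macro_recall, "f1": self.macro_f1},
            "weighted": {"precision": self.weighted_precision,
                         "recall": self.weighted_recall,
                         "f1": self.weighted_f1},
            "confusion": self.confusion.tolist(),
            "label_names": list(self.label_names),
        }


def classification_report(y_true, y_pred, n_classes: int | None = None,
                          label_names: list[str] | None = None) -> EvalReport:
    """Compute per-class precision/recall/F1/support and the confusion matrix.

    Zero-denominator cases (a class never predicted, or absent from
    ``y_true``) yield 0 for the affected metric with a warning.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if n_classes is None:
        n_classes = int(max(y_true.max(), y_pred.max())) + 1
    cm = confusion_matrix(y_true, y_pred, n_classes)
    tp = np.diag(cm).astype(float)
    support = cm.sum(axis=1)
    predicted = cm.sum(axis=0)

    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(predicted > 0, tp / predicted, 0.0)
        recall = np.where(support > 0, tp / support, 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2.0 * precision * recall / denom, 0.0)
    if np.any(predicted == 0):
        warnings.warn(
            "some classes were never predicted; their precision is set to 0",
            UserWarning, stacklevel=2,
        )
    if np.any(support == 0):
        warnings.warn(
            "some classes are absent from y_true; their recall is set to 0",
            UserWarning, stacklevel=2,
        )

    accuracy = float(tp.sum() / len(y_true)) if len(y_true) else 0.0
    if label_names is None:
        label_names = [EXERCISE_NAMES[c] if c < len(EXERCISE_NAMES) else f"class {c}"
                       for c in range(n_classes)]
    return EvalReport(
        accuracy=accuracy, precision=precision, recall=recall, f1=f1,
        support=support, confusion=cm, label_names=list(label_names),
    )


@dataclass
class CVReport:
    """Stratified k-fold accuracy summary (sample sd, n-1 denominator)."""

    k: int
    fold_accuracies: list[float]
    seed: int

    @property
    def mean(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def std(self) -> float:
        return float(np.std(self.fold_accuracies, ddof=1))

    def to_dict(self) -> dict:
        return {"k": self.k, "fold_accuracies": list(self.fold_accuracies),
                "mean": self.mean, "std": self.std, "seed": self.seed}


def kfold_cv(spec: ClassifierSpec, table: FeatureTable, k: int = 10,
             seed: int = 0, use_rfl: bool = False,
             rfl_config: RFLConfig | None = None) -> CVReport:
    """Stratified k-fold accuracy of a classifier, leakage-safe by default.

    With ``use_rfl`` the transfer features are recomputed inside each
    fold: extractors are fitted on the fold's training part only and then
    applied to both parts, so the held-out part never influences feature
    construction.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    counts = table.class_counts()
    if np.any(counts < k):
        small = int(np.flatnonzero(counts < k)[0])
        raise ValueError(
            f"class {small} has {counts[small]} rows, fewer than k={k}"
        )
    rfl_config = rfl_config or RFLConfig()
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    scores: list[float] = []
    for fold, (tr, te) in enumerate(skf.split(table.features, table.labels)):
        X_tr, y_tr = table.features[tr], table.labels[tr]
        X_te, y_te = table.features[te], table.labels[te]
        if use_rfl:
            rfl = RFLTransformer(
                n_estimators=rfl_config.n_estimators,
                max_depth=rfl_config.max_depth,
                criterion=rfl_config.criterion,
                hidden_size=rfl_config.hidden_size,
                window_len=rfl_config.window_len,
                epochs=rfl_config.epochs,
                batch_size=rfl_config.batch_size,
                learning_rate=rfl_config.learning_rate,
                mode="in_sample",
                random_state=rfl_config.seed + fold,
            )
            rfl.fit(X_tr, y_tr)
            X_tr, X_te = rfl.transform(X_tr), rfl.transform(X_te)
        model = train_classifier(spec, X_tr, y_tr)
        scores.append(float(np.mean(predict(model, X_te) == y_te)))
    return CVReport(k=k, fold_accuracies=scores, seed=seed)


@dataclass
class RuntimeLogger:
    """Ordered wall-clock records per pipeline stage; informational only."""

    enabled: bool = True
    records: list[dict] = field(default_factory=list)

    def log(self, stage: str, seconds: float) -> None:
        if self.enabled:
            self.records.append({"stage": stage, "seconds": float(seconds)})

    def timed(self, stage: str):
        """Context manager measuring and logging a stage's duration."""
        logger = self

        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, *exc):
                logger.log(stage, time.perf_counter() - self.t0)
                return False

        return _Timer()
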