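"""Metrics, blocked cross-validation, confusion matrices and curves.

Scoring uses per-class precision, recall and F1 (harmonic mean of the
two), aggregated as the *weighted* F1 — per-class F1 averaged with weights
proportional to each class's true-label support — which is the right
headline number for strongly imbalanced ethograms.  Any metric whose
denominator is empty is defined as 0 (conservative convention).

Cross-validation is five-fold and *non-shuffled*: the window sequence is
cut into five contiguous blocks (remainder to the last block), fold ``i``
tests on block ``i`` and trains on the rest.  Shuffling high-frame-rate
video windows would place near-identical neighbors in train and test and
inflate scores, so it is deliberately avoided.  The last fold — train on
the first 80%, test on the last 20% — doubles as the held-out split used
for per-class reporting and confusion matrices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import (
    confusion_matrix as _sk_confusion,
    f1_score,
    precision_recall_fscore_support,
)

from .classify import ClassifierConfig, ProbabilityTrack, fit, predict_proba
from .features import WindowDataset, make_windows

N_FOLDS = 5


def precision_recall_f1(
    y_true, y_pred, cls: str
) -> tuple[float, float, float]:
    """Precision, recall and F1 of a single class (0 on empty denominators)."""
    y_true = np.asarray(y_true, dtype=object)
    y_pred = np.asarray(y_pred, dtype=object)
    if len(y_true) != len(y_pred):
        raise ValueError(f"length mismatch: {len(y_true)} true vs {len(y_pred)} predicted")
    p, r, f, _ = precision_recall_fscore_support(
        y_true.astype(str), y_pred.astype(str), labels=[cls], zero_division=0
    )
    return float(p[0]), float(r[0]), float(f[0])


def weighted_f1(y_true, y_pred) -> float:
    """Support-weighted mean of per-class F1 scores over true-label supports."""
    y_true = np.asarray(y_true, dtype=object)
    y_pred = np.asarray(y_pred, dtype=object)
    if len(y_true) == 0:
        raise ValueError("cannot score an empty label list")
    if len(y_true) != len(y_pred):
        raise ValueError(f"length mismatch: {len(y_true)} true vs {len(y_pred)} predicted")
    return float(
        f1_score(y_true.astype(str), y_pred.astype(str), average="weighted", zero_division=0)
    )


def confusion(
    y_true, y_pred, class_order: tuple[str, ...]
) -> tuple[np.ndarray, np.ndarray]:
    """Absolute and row-normalized confusion matrices (rows = true class)."""
    y_true = np.asarray(y_true, dtype=object).astype(str)
    y_pred = np.asarray(y_pred, dtype=object).astype(str)
    absolute = _sk_confusion(y_true, y_pred, labels=list(class_order))
    row_sums = absolute.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        relative = np.where(row_sums > 0, absolute / np.maximum(row_sums, 1), 0.0)
    return absolute, relative


def fold_boundaries(n: int, k: int = N_FOLDS) -> list[tuple[int, int]]:
    """Half-open [start, stop) bounds of k contiguous blocks; remainder to the last."""
    if n < k:
        raise ValueError(f"need at least {k} items for {k}-fold CV, got {n}")
    base = n // k
    bounds = [(i * base, (i + 1) * base) for i in range(k - 1)]
    bounds.append(((k - 1) * base, n))
    return bounds


@dataclass
class EvalReport:
    """Cross-validation outcome plus last-fold per-class detail."""

    class_order: tuple[str, ...]
    per_fold_weighted_f1: list[float]
    cv_mean: float
    per_class: dict[str, dict[str, float]]
    confusion_absolute: np.ndarray
    confusion_relative: np.ndarray
    last_fold_true: np.ndarray = field(repr=False, default=None)
    last_fold_pred: np.ndarray = field(repr=False, default=None)
    last_fold_proba: ProbabilityTrack | None = field(repr=False, default=None)
    fold_predictions: list[tuple[np.ndarray, np.ndarray]] = field(
        repr=False, default=None
    )

    @property
    def weighted_f1_last_fold(self) -> float:
        return self.per_fold_weighted_f1[-1]

    def to_dict(self) -> dict:
        return {
            "class_order": list(self.class_order),
            "per_fold_weighted_f1": self.per_fold_weighted_f1,
            "cv_mean": self.cv_mean,
            "per_class": self.per_class,
            "confusion_absolute": self.confusion_absolute.tolist(),
            "confusion_relative": self.confusion_relative.tolist(),
        }

    def save(self, directory: str | Path) -> None:
        """Write the report as JSON plus confusion-matrix CSVs."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "report.json").write_text(
            json.dumps(self.to_dict(), indent=2, sort_keys=True), encoding="utf-8"
        )
        order = list(self.class_order)
        for name, matrix in (
            ("confusion_absolute", self.confusion_absolute),
            ("confusion_relative", self.confusion_relative),
        ):
            pd.DataFrame(matrix, index=order, columns=order).to_csv(
                directory / f"{name}.csv", encoding="utf-8"
            )


def _fit_predict(
    dataset: WindowDataset,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    config: ClassifierConfig,
):
    model = fit(dataset.subset(train_idx), config)
    proba = predict_proba(model, dataset.subset(test_idx))
    pred = np.asarray(
        [proba.classes[i] for i in np.argmax(proba.probs, axis=1)], dtype=object
    )
    return model, proba, pred


def cv5_nonshuffled(dataset: WindowDataset, config: ClassifierConfig | None = None) -> EvalReport:
    """Five-fold blocked CV on a labeled window dataset, in temporal order.

    The report's per-class metrics and confusion matrices come from the
    last fold (first 80% train / last 20% test); the headline ``cv_mean``
    is the arithmetic mean of the five per-fold weighted F1 scores.
    """
    config = config or ClassifierConfig()
    if dataset.labels is None:
        raise ValueError("cross-validation requires a labeled dataset")
    n = len(dataset)
    bounds = fold_boundaries(n)
    all_idx = np.arange(n)

    scores: list[float] = []
    fold_predictions: list[tuple[np.ndarray, np.ndarray]] = []
    proba = None
    for start, stop in bounds:
        test_idx = all_idx[start:stop]
        train_idx = np.concatenate([all_idx[:start], all_idx[stop:]])
        _, proba, pred = _fit_predict(dataset, train_idx, test_idx, config)
        y_true = dataset.labels[test_idx]
        scores.append(weighted_f1(y_true, pred))
        fold_predictions.append((y_true, pred))

    y_true, y_pred = fold_predictions[-1]
    class_order = tuple(sorted(set(dataset.labels.astype(str))))
    per_class = {}
    for cls in class_order:
        p, r, f = precision_recall_f1(y_true, y_pred, cls)
        per_class[cls] = {
            "precision": p,
            "recall": r,
            "f1": f,
            "support": int(np.sum(y_true.astype(str) == cls)),
        }
    absolute, relative = confusion(y_true, y_pred, class_order)
    return EvalReport(
        class_order=class_order,
        per_fold_weighted_f1=scores,
        cv_mean=float(np.mean(scores)),
        per_class=per_class,
        confusion_absolute=absolute,
        confusion_relative=relative,
        last_fold_true=y_true,
        last_fold_pred=y_pred,
        last_fold_proba=proba,
        fold_predictions=fold_predictions,
    )


def validation_curve(
    dataset: WindowDataset,
    hyperparameter: str,
    values,
    config: ClassifierConfig | None = None,
) -> dict:
    """Blocked-CV score as a function of one classifier hyperparameter.

    Supported hyperparameters: ``n_estimators`` (tree count).  Returns, per
    value, the mean and standard deviation over folds plus the raw per-fold
    scores.
    """
    config = config or ClassifierConfig()
    values = list(values)
    if not values:
        raise ValueError("value set must be non-empty")
    if hyperparameter != "n_estimators":
        raise ValueError(
            f"unknown hyperparameter {hyperparameter!r}; supported: n_estimators "
            "(window sizes: use window_size_validation_curve)"
        )
    out = {}
    for value in values:
        report = cv5_nonshuffled(dataset, config.replace(n_estimators=int(value)))
        folds = report.per_fold_weighted_f1
        out[value] = {
            "mean": float(np.mean(folds)),
            "std": float(np.std(folds)),
            "per_fold": folds,
        }
    return out


def window_size_validation_curve(
    features: np.ndarray,
    frame_indices: np.ndarray,
    labels: np.ndarray,
    window_sizes,
    config: ClassifierConfig | None = None,
) -> dict:
    """Blocked-CV score as a function of the sliding-window size.

    Windows are re-cut from the per-frame features for each size, so the
    window counts differ slightly between sizes (longer windows lose more
    positions at run boundaries).
    """
    window_sizes = list(window_sizes)
    if not window_sizes:
        raise ValueError("window_sizes must be non-empty")
    out = {}
    for w in window_sizes:
        dataset = make_windows(features, frame_indices, int(w), labels)
        report = cv5_nonshuffled(dataset, config)
        folds = report.per_fold_weighted_f1
        out[w] = {
            "mean": float(np.mean(folds)),
            "std": float(np.std(folds)),
            "per_fold": folds,
            "report": report,
        }
    return out


def learning_curve(
    dataset: WindowDataset,
    fractions,
    config: ClassifierConfig | None = None,
) -> dict:
    """Blocked-CV score as a function of the training-set size.

    For each fraction, every fold trains on a *contiguous prefix* of its
    training windows (preserving the non-shuffled discipline) and tests on
    its full test block; fraction 1.0 reproduces plain blocked CV.
    """
    config = config or ClassifierConfig()
    if dataset.labels is None:
        raise ValueError("learning curve requires a labeled dataset")
    fractions = list(fractions)
    for f in fractions:
        if not (0.0 < f <= 1.0):
            raise ValueError(f"fractions must lie in (0, 1], got {f}")
    n = len(dataset)
    bounds = fold_boundaries(n)
    all_idx = np.arange(n)

    out = {}
    for frac in fractions:
        scores = []
        for start, stop in bounds:
            test_idx = all_idx[start:stop]
            train_idx = np.concatenate([all_idx[:start], all_idx[stop:]])
            n_train = int(np.ceil(frac * len(train_idx)))
            if n_train < 1:
                raise ValueError(f"fraction {frac} leaves no training windows")
            _, _, pred = _fit_predict(dataset, train_idx[:n_train], test_idx, config)
            scores.append(weighted_f1(dataset.labels[test_idx], pred))
        out[frac] = {
            "mean": float(np.mean(scores)),
            "std": float(np.std(scores)),
            "per_fold": scores,
        }
    return out
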