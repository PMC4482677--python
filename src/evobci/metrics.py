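"""Classifier evaluation: confusion matrices, Cohen's kappa, significance.

Cohen's kappa is the package-wide performance and fitness metric because
it corrects accuracy for agreement expected by chance: with observed
agreement p_o and chance agreement p_e (from the confusion-matrix
marginals),

    kappa = (p_o - p_e) / (1 - p_e).

kappa = 0 is chance-level and 1 is perfect.  Significance against the
null of chance agreement uses the large-sample z-test with the
Fleiss-Cohen-Everitt null standard error

    SE0 = sqrt(p_e + p_e^2 - sum_i p_i. p.i (p_i. + p.i))
          / ((1 - p_e) sqrt(N)).

Also here: the conditional accuracies of the 3-class task (detection of a
squeeze vs laterality once detected) and the stratified k-fold
cross-validation harness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .containers import EpochSet

__all__ = [
    "ConfusionMatrix",
    "EvaluationReport",
    "confusion_matrix",
    "accuracy",
    "cohens_kappa",
    "cohens_kappa_labels",
    "kappa_significance",
    "detection_and_laterality",
    "crossval",
]


@dataclass
class ConfusionMatrix:
    """Counts with rows = true class, columns = predicted class."""

    counts: np.ndarray
    class_names: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if (self.counts.ndim != 2
                or self.counts.shape[0] != self.counts.shape[1]):
            raise ValueError("confusion matrix must be square")
        if (self.counts < 0).any():
            raise ValueError("confusion matrix counts must be >= 0")
        if self.class_names is None:
            self.class_names = [str(i) for i in range(self.counts.shape[0])]
        self.class_names = list(self.class_names)
        if len(self.class_names) != self.counts.shape[0]:
            raise ValueError("one class name per row required")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.counts, index=self.class_names,
                     columns=self.class_names).to_csv(path)


def confusion_matrix(y_true, y_pred, n_classes: int) -> ConfusionMatrix:
    """Pair-count confusion matrix over integer labels in [0, n_classes)."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    for name, y in (("y_true", y_true), ("y_pred", y_pred)):
        if len(y) and (y.min() < 0 or y.max() >= n_classes):
            raise ValueError(f"{name} contains labels outside [0, {n_classes})")
    counts = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(counts, (y_true, y_pred), 1)
    return ConfusionMatrix(counts=counts)


def accuracy(cm: ConfusionMatrix) -> float:
    if cm.n == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts)) / cm.n


def cohens_kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement; returns 0 when p_e == 1 (degenerate)."""
    n = cm.n
    if n < 1:
        raise ValueError("empty confusion matrix")
    c = cm.counts.astype(float)
    p_o = np.trace(c) / n
    p_e = float(c.sum(axis=1) @ c.sum(axis=0)) / n**2
    if p_e >= 1.0 - 1e-15:
        return 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def cohens_kappa_labels(y_true, y_pred, n_classes: int) -> float:
    """Kappa straight from label vectors (training-loop convenience)."""
    return cohens_kappa(confusion_matrix(y_true, y_pred, n_classes))


def kappa_significance(cm: ConfusionMatrix) -> tuple[float, float]:
    """z statistic and two-sided p for H0: kappa = 0.

    Uses the Fleiss-Cohen-Everitt null standard error (see module
    docstring).  Degenerate marginals (p_e = 1) leave the test undefined.
    """
    n = cm.n
    if n < 2:
        raise ValueError("need at least 2 observations")
    c = cm.counts.astype(float)
    p = c / n
    p_row = p.sum(axis=1)
    p_col = p.sum(axis=0)
    p_e = float(p_row @ p_col)
    if p_e >= 1.0 - 1e-15:
        raise ValueError("degenerate marginals: p_e = 1, test undefined")
    se0 = np.sqrt(
        p_e + p_e**2 - float(np.sum(p_row * p_col * (p_row + p_col)))
    ) / ((1.0 - p_e) * np.sqrt(n))
    kappa = cohens_kappa(cm)
    z = kappa / se0
    p_value = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(min(p_value, 1.0))


def detection_and_laterality(
    cm: ConfusionMatrix, condition_on_detected: bool = True
) -> tuple[float, float]:
    """Conditional accuracies of the 3-class (LEFT, RIGHT, NO_MOVEMENT) task.

    Returns ``(acc_laterality_given_detected, acc_detection)``:
    detection = fraction of true-movement trials predicted as movement;
    laterality = fraction with the correct side among movement trials
    predicted as movement (or among all movement trials when
    ``condition_on_detected=False``).
    """
    if cm.n_classes != 3:
        raise ValueError("requires a 3-class confusion matrix")
    c = cm.counts.astype(float)
    movement_total = c[:2].sum()
    if movement_total == 0:
        raise ValueError("no movement trials in the matrix")
    predicted_movement = c[:2, :2].sum()
    acc_detection = predicted_movement / movement_total
    correct_side = c[0, 0] + c[1, 1]
    denom = predicted_movement if condition_on_detected else movement_total
    if denom == 0:
        return float("nan"), float(acc_detection)
    return float(correct_side / denom), float(acc_detection)


@dataclass
class EvaluationReport:
    """Pooled and per-fold evaluation of a classifier."""

    confusion: ConfusionMatrix
    accuracy: float
    kappa: float
    kappa_se0: float
    p_value: float
    per_fold: list["EvaluationReport"] | None = None
    kappa_mean: float | None = None
    kappa_sd: float | None = None
    accuracy_mean: float | None = None
    accuracy_sd: float | None = None
    fold_models: list | None = None
    fold_test_indices: list[np.ndarray] | None = None
    meta: dict = field(default_factory=dict)

    @property
    def significant_001(self) -> bool:
        """The paper-style ** flag: p < 0.01."""
        return self.p_value < 0.01

    def to_json(self, path=None) -> str:
        doc = {
            "class_names": list(self.confusion.class_names),
            "confusion": self.confusion.counts.tolist(),
            "accuracy": self.accuracy,
            "kappa": self.kappa,
            "kappa_se0": self.kappa_se0,
            "p_value": self.p_value,
            "significant_001": self.significant_001,
            "meta": self.meta,
        }
        for name in ("kappa_mean", "kappa_sd", "accuracy_mean", "accuracy_sd"):
            if getattr(self, name) is not None:
                doc[name] = getattr(self, name)
        if self.per_fold:
            doc["per_fold"] = [
                {"kappa": f.kappa, "accuracy": f.accuracy,
                 "confusion": f.confusion.counts.tolist()}
                for f in self.per_fold
            ]
        text = json.dumps(doc, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def evaluate_predictions(y_true, y_pred, n_classes: int,
                         class_names=None) -> EvaluationReport:
    """Single-split EvaluationReport from label vectors."""
    cm = confusion_matrix(y_true, y_pred, n_classes)
    if class_names is not None:
        cm.class_names = list(class_names)
    kappa = cohens_kappa(cm)
    try:
        z, p = kappa_significance(cm)
        se0 = kappa / z if z != 0 else float("nan")
    except ValueError:
        se0, p = float("nan"), float("nan")
    return EvaluationReport(
        confusion=cm, accuracy=accuracy(cm), kappa=kappa,
        kappa_se0=se0, p_value=p,
    )


def crossval(
    data: EpochSet,
    pipeline: Callable[[EpochSet, int], Callable[[np.ndarray], np.ndarray]],
    k: int = 5,
    seed: int = 0,
) -> EvaluationReport:
    """Stratified k-fold cross-validation of a training pipeline.

    ``pipeline(train_set, seed)`` must return a predictor mapping
    flattened-epoch rows to integer labels.  Test folds are disjoint and
    cover every epoch exactly once; any internal train/validation split
    happens inside the pipeline on the training 80% only, so test data
    never leaks into training or early stopping.
    """
    from sklearn.model_selection import StratifiedKFold

    if k < 2:
        raise ValueError("k must be >= 2")
    y = data.labels
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError(
            f"every class needs >= k={k} members (smallest has {counts.min()})"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % 2**32)
    folds, fold_models, fold_test = [], [], []
    y_true_all, y_pred_all = [], []
    for fold_i, (tr, te) in enumerate(skf.split(np.zeros(len(y)), y)):
        predictor = pipeline(data.subset(tr), seed + 1000 * (fold_i + 1))
        y_pred = np.asarray(predictor(data.flatten()[te]))
        rep = evaluate_predictions(y[te], y_pred, data.n_classes,
                                   data.class_names)
        folds.append(rep)
        fold_models.append(getattr(predictor, "model", predictor))
        fold_test.append(te)
        y_true_all.append(y[te])
        y_pred_all.append(y_pred)
    pooled = evaluate_predictions(
        np.concatenate(y_true_all), np.concatenate(y_pred_all),
        data.n_classes, data.class_names,
    )
    pooled.per_fold = folds
    pooled.kappa_mean = float(np.mean([f.kappa for f in folds]))
    pooled.kappa_sd = float(np.std([f.kappa for f in folds], ddof=1))
    pooled.accuracy_mean = float(np.mean([f.accuracy for f in folds]))
    pooled.accuracy_sd = float(np.std([f.accuracy for f in folds], ddof=1))
    pooled.fold_models = fold_models
    pooled.fold_test_indices = fold_test
    return pooled
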