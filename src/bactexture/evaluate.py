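"""Evaluation protocols: repeated equal splits and class-count scalability.

Protocol 1 repeats a balanced per-class train/test split (default 10/10)
a number of times (default 25); every repeat refits the representation
encoder on the training half only, trains the classifier, and scores the
test half.  Accuracy is the fraction of correctly classified test
images; per-repeat accuracies are aggregated as mean +/- std (reported
as percent) and confusion counts are accumulated across repeats with the
convention that entry (i, j) counts observations of true class i
predicted as class j.

Protocol 2 draws random n-class subsets for a ladder of n values,
evaluates the one-vs-all linear SVM on each, and extrapolates accuracy
to a larger class count with ordinary least squares (one line per
repeat; prediction = mean of the per-repeat predictions at the target,
uncertainty = their standard deviation).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

from .classify import make_classifier
from .io import DatasetIndex, LabeledImage, make_split
from .representation import RepresentationBuilder

Loader = Callable[[str], LabeledImage]


def confusion_matrix(true_labels: Sequence, predicted_labels: Sequence,
                     classes: Sequence) -> np.ndarray:
    """C x C counts; entry (i, j) = observations of class i predicted j."""
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label lists must have equal length")
    known = set(classes)
    for lab in list(true_labels) + list(predicted_labels):
        if lab not in known:
            raise ValueError(f"unknown label {lab!r}")
    return _sk_confusion(true_labels, predicted_labels, labels=list(classes))


def per_class_accuracy(confusion: np.ndarray, classes: Sequence | None = None) -> dict:
    """Diagonal over row sums, keyed by class (or row index)."""
    confusion = np.asarray(confusion)
    row_sums = confusion.sum(axis=1)
    if np.any(row_sums == 0):
        raise ValueError("confusion matrix has an empty row")
    acc = np.diag(confusion) / row_sums
    keys = list(classes) if classes is not None else list(range(len(acc)))
    return {k: float(a) for k, a in zip(keys, acc)}


@dataclass
class EvaluationReport:
    """Aggregated repeated-split results."""

    classes: list[str]
    per_repeat_accuracies: list[float]
    confusion: np.ndarray
    config: dict = field(default_factory=dict)

    @property
    def mean_pct(self) -> float:
        return float(np.mean(self.per_repeat_accuracies) * 100)

    @property
    def std_pct(self) -> float:
        return float(np.std(self.per_repeat_accuracies) * 100)

    @property
    def per_class(self) -> dict:
        return per_class_accuracy(self.confusion, self.classes)

    @property
    def overall_accuracy(self) -> float:
        return float(np.trace(self.confusion) / self.confusion.sum())

    def summary(self) -> str:
        return f"{self.mean_pct:.2f} ±{self.std_pct:.2f}%"

    def to_json(self) -> str:
        return json.dumps({
            "classes": self.classes,
            "per_repeat_accuracies": self.per_repeat_accuracies,
            "mean_pct": round(self.mean_pct, 10),
            "std_pct": round(self.std_pct, 10),
            "per_class_accuracy": {k: round(v, 10) for k, v in self.per_class.items()},
            "confusion": self.confusion.tolist(),
            "config": self.config,
        }, sort_keys=True, indent=1)


def _evaluate_once(index: DatasetIndex, load: Loader, builder: RepresentationBuilder,
                   classifier, per_class_train: int, seed: int):
    """One split -> (accuracy, true labels, predicted labels)."""
    plan = make_split(index, per_class_train=per_class_train, seed=seed)
    train = [(load(src), lab) for src, lab in plan.train_entries()]
    test = [(load(src), lab) for src, lab in plan.test_entries()]
    builder.fit([img for img, _ in train])
    X_train = builder.transform([img for img, _ in train])
    X_test = builder.transform([img for img, _ in test])
    y_train = [lab for _, lab in train]
    y_test = [lab for _, lab in test]
    classifier.fit(X_train, y_train)
    y_pred = list(classifier.predict(X_test))
    acc = float(np.mean([p == t for p, t in zip(y_pred, y_test)]))
    return acc, y_test, y_pred


def run_repeated_eval(
    index: DatasetIndex,
    load: Loader,
    builder_factory: Callable[[], RepresentationBuilder],
    classifier_factory: Callable[[], object],
    per_class_train: int = 10,
    repeats: int = 25,
    seed: int = 0,
) -> EvaluationReport:
    """Protocol 1: repeated balanced-split evaluation.

    Each repeat r uses split seed ``seed + 1000 * r``; the encoder is
    fitted on that repeat's training images only (no test leakage).
    Factories must return fresh (unfitted) objects so repeats stay
    independent.
    """
    accuracies: list[float] = []
    confusion = np.zeros((len(index.classes), len(index.classes)), dtype=np.int64)
    for r in range(repeats):
        try:
            acc, y_true, y_pred = _evaluate_once(
                index, load, builder_factory(), classifier_factory(),
                per_class_train, seed + 1000 * r)
        except Exception as exc:
            raise RuntimeError(f"evaluation failed at repeat {r}: {exc}") from exc
        accuracies.append(acc)
        confusion += confusion_matrix(y_true, y_pred, index.classes)
    return EvaluationReport(
        classes=list(index.classes),
        per_repeat_accuracies=accuracies,
        confusion=confusion,
        config={"per_class_train": per_class_train, "repeats": repeats, "seed": seed},
    )


@dataclass
class ScalabilityResult:
    """Accuracies on random n-class subsets, for extrapolation."""

    n_values: list[int]
    accuracies: np.ndarray  # len(n_values) x repeats, fractions
    seed: int
    config: dict = field(default_factory=dict)

    def mean_by_n(self) -> np.ndarray:
        return self.accuracies.mean(axis=1)

    def to_json(self) -> str:
        return json.dumps({
            "n_values": self.n_values,
            "accuracies": self.accuracies.tolist(),
            "mean_by_n": self.mean_by_n().tolist(),
            "seed": self.seed,
            "config": self.config,
        }, sort_keys=True, indent=1)


def scalability_experiment(
    index: DatasetIndex,
    load: Loader,
    builder_factory: Callable[[], RepresentationBuilder],
    classifier_factory: Callable[[], object] | None = None,
    n_values: Sequence[int] = tuple(range(3, 32, 3)),
    repeats: int = 25,
    per_class_train: int = 10,
    seed: int = 0,
) -> ScalabilityResult:
    """Protocol 2: accuracy on seeded random n-class subsets.

    Each (n, repeat) cell draws its own class subset and split; the
    classifier defaults to the one-vs-all linear SVM with C = 1.
    """
    n_values = sorted(int(n) for n in n_values)
    if max(n_values) > len(index.classes):
        raise ValueError(f"largest n {max(n_values)} exceeds class count "
                         f"{len(index.classes)}")
    if classifier_factory is None:
        classifier_factory = lambda: make_classifier("original")
    acc = np.zeros((len(n_values), repeats))
    for i, n in enumerate(n_values):
        for r in range(repeats):
            rng = np.random.default_rng([seed, i, r])
            chosen = [index.classes[j] for j in
                      sorted(rng.choice(len(index.classes), n, replace=False))]
            sub = index.subset(chosen)
            try:
                acc[i, r], _, _ = _evaluate_once(
                    sub, load, builder_factory(), classifier_factory(),
                    per_class_train, int(rng.integers(2**31)))
            except Exception as exc:
                raise RuntimeError(
                    f"scalability run failed at n={n}, repeat {r}: {exc}") from exc
    return ScalabilityResult(
        n_values=list(n_values), accuracies=acc, seed=seed,
        config={"repeats": repeats, "per_class_train": per_class_train})


@dataclass
class Extrapolation:
    """OLS extrapolation of subset accuracy to a larger class count."""

    target_classes: int
    prediction_pct: float
    uncertainty_pct: float
    slope: float  # pooled fit, percent per class
    intercept: float  # pooled fit, percent

    def to_json(self) -> str:
        return json.dumps({
            "target_classes": self.target_classes,
            "prediction_pct": round(self.prediction_pct, 10),
            "uncertainty_pct": round(self.uncertainty_pct, 10),
            "slope": round(self.slope, 12),
            "intercept": round(self.intercept, 12),
        }, sort_keys=True, indent=1)


def linear_extrapolation(result: ScalabilityResult,
                         target_classes: int = 100) -> Extrapolation:
    """Least-squares accuracy-vs-n lines, extrapolated to ``target_classes``.

    One line is fitted per repeat (that repeat's accuracy at every n);
    the reported prediction is the mean of the per-repeat predictions at
    the target and the uncertainty is their standard deviation.  The
    slope/intercept of the pooled fit over all points are also reported.
    All quantities are on the percent scale.
    """
    n = np.asarray(result.n_values, dtype=float)
    if len(np.unique(n)) < 2:
        raise ValueError("need at least 2 distinct n values to fit a line")
    acc_pct = result.accuracies * 100
    preds = []
    for r in range(acc_pct.shape[1]):
        slope, intercept = np.polyfit(n, acc_pct[:, r], 1)
        preds.append(slope * target_classes + intercept)
    pooled = np.polyfit(np.repeat(n, acc_pct.shape[1]), acc_pct.ravel(), 1)
    return Extrapolation(
        target_classes=target_classes,
        prediction_pct=float(np.mean(preds)),
        uncertainty_pct=float(np.std(preds)),
        slope=float(pooled[0]),
        intercept=float(pooled[1]),
    )
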