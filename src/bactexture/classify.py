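"""Classifier family: one-vs-all linear SVM, Bayes-optimized kernel SVMs,
and an AdaBoost tree ensemble.

The "original" classifier is a one-vs-all linear SVM with C = 1 whose
prediction is the argmax of the per-class decision values (ties resolved
toward the lowest class index).  The alternatives are one-vs-one SVMs
(linear / polynomial / RBF kernels) and boosted depth-limited decision
trees; their hyperparameters are tuned by Bayesian optimization of the
mean 5-fold stratified cross-validation accuracy on the training set.

Features are standardized (training-set mean/variance) inside every
classifier; the scaler is part of the fitted state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import joblib
import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import AdaBoostClassifier
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, LinearSVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

from .io import class_sort_key

VALID_KERNELS = ("linear", "poly", "rbf")


@dataclass
class SvmSpec:
    """SVM configuration: multiclass scheme, kernel and parameters."""

    scheme: str = "one-vs-one"
    kernel: str = "linear"
    C: float = 1.0
    degree: int = 3
    gamma: float | str = "scale"

    def __post_init__(self) -> None:
        if self.scheme not in ("one-vs-all", "one-vs-one"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.kernel not in VALID_KERNELS:
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.kernel == "poly" and self.degree not in (2, 3, 4):
            raise ValueError("polynomial degree must be 2, 3 or 4")
        if self.kernel == "rbf" and not (self.gamma == "scale" or self.gamma > 0):
            raise ValueError("gamma must be positive")


def _encode_labels(y, classes):
    lut = {c: i for i, c in enumerate(classes)}
    try:
        return np.array([lut[v] for v in y])
    except KeyError as exc:
        raise ValueError(f"label {exc.args[0]!r} not in class list") from exc


class _ClassOrderMixin:
    """Shared label bookkeeping: classes ordered by numeric id."""

    def _resolve_classes(self, y):
        classes = getattr(self, "classes", None)
        if classes is None:
            classes = sorted(set(y), key=class_sort_key)
        if len(classes) < 2:
            raise ValueError("need at least 2 classes")
        self.classes_ = np.asarray(classes, dtype=object)
        return _encode_labels(y, classes)

    def _check_dim(self, X):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features_in_:
            raise ValueError(f"feature dim {X.shape[1]} != trained dim "
                             f"{self.n_features_in_}")
        return X

    def save(self, path) -> None:
        joblib.dump({"format": "bactexture-classifier", "version": 1,
                     "model": self}, path)

    @staticmethod
    def load(path):
        bundle = joblib.load(path)
        if bundle.get("format") != "bactexture-classifier" or bundle.get("version") != 1:
            raise ValueError("unrecognized or mismatched classifier bundle version")
        return bundle["model"]


class OriginalClassifier(_ClassOrderMixin, BaseEstimator, ClassifierMixin):
    """One-vs-all linear SVM, C = 1 — the reference texture classifier.

    One binary machine per class; predict() takes the argmax of the
    decision values, with ties broken toward the lowest class index.
    """

    def __init__(self, C: float = 1.0, classes: list | None = None):
        self.C = C
        self.classes = classes

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y_enc = self._resolve_classes(y)
        self.n_features_in_ = X.shape[1]
        self.pipeline_ = Pipeline([
            ("scale", StandardScaler()),
            ("svm", LinearSVC(C=self.C, random_state=0)),
        ]).fit(X, y_enc)
        return self

    def decision_function(self, X):
        check_is_fitted(self, "pipeline_")
        scores = self.pipeline_.decision_function(self._check_dim(X))
        if scores.ndim == 1:  # binary: expand to per-class columns
            scores = np.stack([-scores, scores], axis=1)
        # LinearSVC orders columns by encoded label = class-list position
        return scores

    def predict(self, X):
        scores = self.decision_function(X)
        return self.classes_[np.argmax(scores, axis=1)]


def bayes_optimize(objective, space, n_calls: int = 25, seed: int = 0,
                   n_initial: int = 8, n_candidates: int = 512):
    """Maximize ``objective`` over a box with a GP surrogate and EI.

    ``space`` is a list of dimensions: ("float", lo, hi) sampled
    continuously or ("int", lo, hi) sampled on integers.  The first
    ``n_initial`` evaluations are seeded random draws; each later point
    maximizes expected improvement over a random candidate set.
    Deterministic for a fixed seed.  Returns (best_x, best_y, trace).
    """
    if n_calls < 5:
        raise ValueError("optimization budget must be at least 5 evaluations")
    rng = np.random.default_rng(seed)

    def draw(n):
        cols = []
        for kind, lo, hi in space:
            if kind == "int":
                cols.append(rng.integers(lo, hi + 1, size=n).astype(float))
            else:
                cols.append(rng.uniform(lo, hi, size=n))
        return np.stack(cols, axis=1)

    X_obs, y_obs, trace = [], [], []

    def evaluate(x):
        y = objective([int(round(v)) if kind == "int" else float(v)
                       for (kind, _, _), v in zip(space, x)])
        if not np.isfinite(y):
            return  # skip non-finite scores
        X_obs.append(x)
        y_obs.append(y)
        trace.append({"x": [float(v) for v in x], "score": float(y)})

    for x in draw(min(n_initial, n_calls)):
        evaluate(x)
    widths = np.array([hi - lo for _, lo, hi in space], dtype=float)
    kernel = ConstantKernel(1.0) * Matern(length_scale=widths / 2, nu=2.5) \
        + WhiteKernel(noise_level=1e-4)
    while len(trace) < n_calls:
        gp = GaussianProcessRegressor(kernel=kernel, normalize_y=True,
                                      random_state=int(rng.integers(2**31)))
        gp.fit(np.asarray(X_obs), np.asarray(y_obs))
        cand = draw(n_candidates)
        mu, sd = gp.predict(cand, return_std=True)
        best = max(y_obs)
        sd = np.maximum(sd, 1e-12)
        z = (mu - best) / sd
        from scipy.stats import norm as _norm
        ei = (mu - best) * _norm.cdf(z) + sd * _norm.pdf(z)
        evaluate(cand[int(np.argmax(ei))])
    i_best = int(np.argmax(y_obs))
    best_x = [int(round(v)) if kind == "int" else float(v)
              for (kind, _, _), v in zip(space, X_obs[i_best])]
    return best_x, float(y_obs[i_best]), trace


def _cv_accuracy(estimator, X, y_enc, seed: int, folds: int = 5) -> float:
    n_per_class = np.bincount(y_enc).min()
    cv = StratifiedKFold(n_splits=min(folds, max(2, n_per_class)), shuffle=True,
                         random_state=seed)
    return float(np.mean(cross_val_score(estimator, X, y_enc, cv=cv)))


class OptimizedSvmClassifier(_ClassOrderMixin, BaseEstimator, ClassifierMixin):
    """One-vs-one SVM with Bayes-optimized hyperparameters.

    Search space: log10 C in [-3, 3]; plus log10 gamma in [-4, 1] for the
    RBF kernel and degree in {2, 3, 4} for the polynomial kernel.  The
    objective is mean 5-fold stratified CV accuracy on the training set;
    the final model is refitted on all training data at the optimum.
    """

    def __init__(self, kernel: str = "linear", budget: int = 25, seed: int = 0,
                 classes: list | None = None):
        self.kernel = kernel
        self.budget = budget
        self.seed = seed
        self.classes = classes

    def _make_svc(self, params):
        kw = dict(kernel=self.kernel, C=10.0 ** params[0], random_state=0)
        if self.kernel == "rbf":
            kw["gamma"] = 10.0 ** params[1]
        elif self.kernel == "poly":
            kw["degree"] = int(params[1])
        return Pipeline([("scale", StandardScaler()), ("svm", SVC(**kw))])

    def fit(self, X, y):
        if self.kernel not in VALID_KERNELS:
            raise ValueError(f"unknown kernel {self.kernel!r}")
        X = np.asarray(X, dtype=np.float64)
        y_enc = self._resolve_classes(y)
        self.n_features_in_ = X.shape[1]
        space = [("float", -3.0, 3.0)]
        if self.kernel == "rbf":
            space.append(("float", -4.0, 1.0))
        elif self.kernel == "poly":
            space.append(("int", 2, 4))
        best, score, trace = bayes_optimize(
            lambda p: _cv_accuracy(self._make_svc(p), X, y_enc, self.seed),
            space, n_calls=self.budget, seed=self.seed)
        self.best_params_ = best
        self.best_cv_score_ = score
        self.optimizer_trace_ = trace
        self.pipeline_ = self._make_svc(best).fit(X, y_enc)
        return self

    def predict(self, X):
        check_is_fitted(self, "pipeline_")
        return self.classes_[self.pipeline_.predict(self._check_dim(X))]


class BoostedTreesClassifier(_ClassOrderMixin, BaseEstimator, ClassifierMixin):
    """Multiclass AdaBoost (SAMME) over depth-limited decision trees.

    When ``n_estimators`` / ``max_depth`` are not given they are Bayes-
    optimized (same CV protocol as the SVM variants) over
    n_estimators in [50, 300] and depth in {1, 2, 3}.
    """

    def __init__(self, n_estimators: int | None = None, max_depth: int | None = None,
                 budget: int = 25, seed: int = 0, classes: list | None = None):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.budget = budget
        self.seed = seed
        self.classes = classes

    def _make(self, n_estimators, max_depth):
        return Pipeline([
            ("scale", StandardScaler()),
            ("ada", AdaBoostClassifier(
                estimator=DecisionTreeClassifier(max_depth=max_depth, random_state=0),
                n_estimators=n_estimators, random_state=self.seed)),
        ])

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y_enc = self._resolve_classes(y)
        self.n_features_in_ = X.shape[1]
        if self.n_estimators is not None and self.max_depth is not None:
            n_est, depth = self.n_estimators, self.max_depth
            self.optimizer_trace_ = []
        else:
            best, score, trace = bayes_optimize(
                lambda p: _cv_accuracy(self._make(p[0], p[1]), X, y_enc, self.seed),
                [("int", 50, 300), ("int", 1, 3)],
                n_calls=self.budget, seed=self.seed)
            n_est, depth = best
            self.best_cv_score_ = score
            self.optimizer_trace_ = trace
        self.n_estimators_, self.max_depth_ = n_est, depth
        self.pipeline_ = self._make(n_est, depth).fit(X, y_enc)
        return self

    def predict(self, X):
        check_is_fitted(self, "pipeline_")
        return self.classes_[self.pipeline_.predict(self._check_dim(X))]


#: classifier tags accepted by the evaluation protocols and the CLI
CLASSIFIER_TAGS = ("original", "linear", "poly", "rbf", "rf-adaboost")


def make_classifier(tag: str, seed: int = 0, budget: int = 25,
                    classes: list | None = None):
    """Instantiate a classifier from its protocol tag."""
    if tag == "original":
        return OriginalClassifier(C=1.0, classes=classes)
    if tag in ("linear", "poly", "rbf"):
        return OptimizedSvmClassifier(kernel=tag, budget=budget, seed=seed,
                                      classes=classes)
    if tag == "rf-adaboost":
        return BoostedTreesClassifier(budget=budget, seed=seed, classes=classes)
    raise ValueError(f"unknown classifier tag {tag!r}; choose from {CLASSIFIER_TAGS}")
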