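"""Feed-forward backpropagation neural network and evaluation machinery.

The classifier is a single-hidden-layer network (10 logistic units by
default, sigmoid output) trained by full-batch backpropagation on binary
cross-entropy with Adam-style adaptive steps; weights are seeded so a
given configuration is deterministic.  Inputs are standardized internally.
Evaluation reports the five confusion-matrix metrics with stressed
(label 1) as the positive class, over a stratified 4:1 hold-out split or
stratified 10-fold cross-validation.  SVM and random-forest baselines wrap
scikit-learn under the same split/metrics contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.svm import SVC

from .errors import ConfigurationError, EvaluationError, TrainingError


@dataclass(frozen=True)
class NetConfig:
    hidden_units: int = 10
    activation: str = "logistic"  # or "tanh"
    learning_rate: float = 0.05
    epochs: int = 300
    seed: int = 0
    train_fraction: float = 0.8  # the 4:1 hold-out split

    def validate(self) -> None:
        if self.hidden_units < 1 or self.epochs < 1:
            raise ConfigurationError("hidden_units and epochs must be positive")
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be positive")
        if self.activation not in ("logistic", "tanh"):
            raise ConfigurationError(
                f"unknown activation {self.activation!r}"
            )
        if not 0.0 < self.train_fraction < 1.0:
            raise ConfigurationError("train_fraction must lie in (0, 1)")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class FFBPNN:
    """Single-hidden-layer feed-forward net trained by backpropagation."""

    def __init__(self, config: NetConfig | None = None) -> None:
        self.config = config or NetConfig()
        self.config.validate()
        self._fitted = False

    def fit(self, X: np.ndarray, y: np.ndarray) -> "FFBPNN":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[0] != y.size:
            raise TrainingError("X must be 2-D with one row per label")
        classes = np.unique(y)
        if classes.size < 2:
            raise TrainingError("training data contains a single class")
        if not np.all(np.isfinite(X)):
            raise TrainingError("features must be finite")

        self._mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        self._sd = sd
        Z = (X - self._mu) / self._sd

        n, d = Z.shape
        h = self.config.hidden_units
        rng = np.random.default_rng(self.config.seed)
        limit1 = np.sqrt(6.0 / (d + h))
        limit2 = np.sqrt(6.0 / (h + 1))
        W1 = rng.uniform(-limit1, limit1, (d, h))
        b1 = np.zeros(h)
        W2 = rng.uniform(-limit2, limit2, (h, 1))
        b2 = np.zeros(1)

        params = [W1, b1, W2, b2]
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        lr = self.config.learning_rate
        tanh = self.config.activation == "tanh"
        yt = y[:, None]

        for t in range(1, self.config.epochs + 1):
            z1 = Z @ W1 + b1
            H = np.tanh(z1) if tanh else _sigmoid(z1)
            p = _sigmoid(H @ W2 + b2)
            # dL/dz2 for mean binary cross-entropy
            dz2 = (p - yt) / n
            gW2 = H.T @ dz2
            gb2 = dz2.sum(axis=0)
            dH = dz2 @ W2.T
            dz1 = dH * (1.0 - H**2) if tanh else dH * H * (1.0 - H)
            gW1 = Z.T @ dz1
            gb1 = dz1.sum(axis=0)
            for p_, m_, v_, g in zip(params, m, v, (gW1, gb1, gW2, gb2)):
                m_ *= beta1
                m_ += (1 - beta1) * g
                v_ *= beta2
                v_ += (1 - beta2) * g**2
                mhat = m_ / (1 - beta1**t)
                vhat = v_ / (1 - beta2**t)
                p_ -= lr * mhat / (np.sqrt(vhat) + eps)

        self._W1, self._b1, self._W2, self._b2 = W1, b1, W2, b2
        self._fitted = True
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if not self._fitted:
            raise EvaluationError("model is not fitted")
        Z = (np.asarray(X, dtype=float) - self._mu) / self._sd
        H = (
            np.tanh(Z @ self._W1 + self._b1)
            if self.config.activation == "tanh"
            else _sigmoid(Z @ self._W1 + self._b1)
        )
        return _sigmoid(H @ self._W2 + self._b2).ravel()

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X) >= 0.5).astype(int)


@dataclass(frozen=True)
class Metrics:
    """Confusion counts and the five derived metrics (positive = stressed)."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def accuracy(self) -> float:
        total = self.tp + self.fp + self.fn + self.tn
        return (self.tp + self.tn) / total if total else 0.0

    @property
    def precision(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else 0.0

    @property
    def recall(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else 0.0

    @property
    def specificity(self) -> float:
        d = self.tn + self.fp
        return self.tn / d if d else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0

    @classmethod
    def from_predictions(
        cls, y_true: np.ndarray, y_pred: np.ndarray
    ) -> "Metrics":
        y_true = np.asarray(y_true).astype(int)
        y_pred = np.asarray(y_pred).astype(int)
        return cls(
            tp=int(np.sum((y_pred == 1) & (y_true == 1))),
            fp=int(np.sum((y_pred == 1) & (y_true == 0))),
            fn=int(np.sum((y_pred == 0) & (y_true == 1))),
            tn=int(np.sum((y_pred == 0) & (y_true == 0))),
        )

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "specificity": self.specificity,
            "f1": self.f1,
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "tn": self.tn,
        }


def evaluate(model, X_test: np.ndarray, y_test: np.ndarray) -> Metrics:
    """Confusion-matrix metrics of a fitted model on a test set."""
    y_test = np.asarray(y_test)
    if y_test.size == 0:
        raise EvaluationError("test set is empty")
    return Metrics.from_predictions(y_test, model.predict(X_test))


def stratified_split(
    y: np.ndarray, train_fraction: float = 0.8, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive, class-stratified train/test index split."""
    idx = np.arange(len(y))
    train, test = train_test_split(
        idx, train_size=train_fraction, stratify=y, random_state=seed
    )
    return np.sort(train), np.sort(test)


def train_ffbpnn(
    X: np.ndarray, y: np.ndarray, config: NetConfig | None = None
) -> FFBPNN:
    """Fit the feed-forward backpropagation network."""
    return FFBPNN(config).fit(X, y)


@dataclass
class CVResult:
    fold_metrics: list[Metrics]
    mean: dict[str, float]
    test_indices: list[np.ndarray] = field(default_factory=list)


def mean_metrics(metrics: Sequence[Metrics]) -> dict[str, float]:
    keys = ("accuracy", "precision", "recall", "specificity", "f1")
    return {
        k: float(np.mean([getattr(m, k) for m in metrics])) for k in keys
    }


def kfold_cv(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 10,
    config: NetConfig | None = None,
) -> CVResult:
    """Stratified k-fold cross-validation of the FFBPNN."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if k > len(y):
        raise ConfigurationError(f"k = {k} exceeds n = {len(y)}")
    if np.unique(y).size < 2:
        raise TrainingError("need both classes for cross-validation")
    config = config or NetConfig()
    # stratification needs every class in every fold; at the leave-one-out
    # limit (k exceeding the smaller class) fall back to plain K-fold
    min_class = int(np.bincount(y).min())
    if k <= min_class:
        splitter = StratifiedKFold(
            n_splits=k, shuffle=True, random_state=config.seed
        )
    else:
        from sklearn.model_selection import KFold

        splitter = KFold(n_splits=k, shuffle=True, random_state=config.seed)
    folds: list[Metrics] = []
    test_indices: list[np.ndarray] = []
    for train_idx, test_idx in splitter.split(X, y):
        model = FFBPNN(config).fit(X[train_idx], y[train_idx])
        folds.append(evaluate(model, X[test_idx], y[test_idx]))
        test_indices.append(test_idx)
    return CVResult(
        fold_metrics=folds, mean=mean_metrics(folds), test_indices=test_indices
    )


def baseline_classifiers(
    X: np.ndarray,
    y: np.ndarray,
    config: NetConfig | None = None,
) -> dict[str, Metrics]:
    """SVM and random-forest baselines under the same split and metrics.

    The split seed comes from ``config.seed`` so all classifiers see the
    identical train/test partition.
    """
    config = config or NetConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if np.unique(y).size < 2:
        raise TrainingError("need both classes")
    train, test = stratified_split(y, config.train_fraction, config.seed)
    results: dict[str, Metrics] = {}
    for name, model in (
        ("svm", SVC(random_state=config.seed)),
        ("rf", RandomForestClassifier(n_estimators=100, random_state=config.seed)),
    ):
        model.fit(X[train], y[train])
        results[name] = evaluate(model, X[test], y[test])
    return results
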