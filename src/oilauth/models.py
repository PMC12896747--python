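"""Qualitative classifiers and the quantitative composition model.

Five classifier kinds are supported — a 1D Conv–Attention–MLP network
(CNN), Random Forest, linear SVM, logistic regression and gradient-boosted
trees — with the fixed, seeded hyperparameters used throughout
(RF/GBT: 100 estimators, GBT lr 0.1 depth 3, SVM linear balanced; all
random_state 42; 8:2 train/test split, split seed 42). The quantifier is
the same dual-branch network with a 5-way softmax head trained with MSE so
its predictions live on the composition simplex.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from sklearn.svm import SVC

from ._nn import ConvAttentionNet
from .io_msdata import OIL_CLASSES

CLASSIFIER_KINDS = ("cnn", "rf", "svm", "lr", "gbt")
BINARY_POSITIVE = "adulterated"
BINARY_NEGATIVE = "pure CAO"

DEFAULT_SPLIT_FRACTION = 0.2
DEFAULT_SPLIT_SEED = 42


@dataclass(frozen=True)
class ClassifierSpec:
    """Which classifier to train and with what (seeded) hyperparameters."""

    kind: str
    seed: int = 42
    n_estimators: int = 100          # rf / gbt
    learning_rate: float = 0.1       # gbt
    max_depth: int = 3               # gbt
    epochs: int = 200                # cnn
    batch_size: int = 32
    nn_lr: float = 1e-3
    patience: int = 20

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(f"unknown classifier kind {self.kind!r}")


@dataclass(frozen=True)
class QuantifierSpec:
    """Training configuration of the Conv–Attention–MLP quantifier.

    The network outputs the five oil volume fractions through a softmax,
    is trained with Adam on an MSE loss, holds out ``val_fraction`` of the
    training data for early stopping, and decays the learning rate on a
    validation plateau.
    """

    seed: int = 42
    epochs: int = 200
    batch_size: int = 32
    lr: float = 1e-3
    patience: int = 20
    val_fraction: float = 0.2


def binary_label(class_label: str) -> str:
    """Map a composition class label onto the pure-vs-adulterated task.

    Pure camellia oil is the negative class; every mixture containing an
    adulterant — and every pure non-CAO oil — counts as adulterated."""
    return BINARY_NEGATIVE if class_label == "CAO" else BINARY_POSITIVE


def task_labels(records, task: str) -> np.ndarray:
    if task == "binary":
        return np.array([binary_label(r.label) for r in records])
    if task == "multiclass":
        return np.array([r.label for r in records])
    raise ValueError(f"unknown task {task!r}")


def split_data(records, test_fraction: float = DEFAULT_SPLIT_FRACTION,
               seed: int = DEFAULT_SPLIT_SEED, labels=None):
    """Stratified, disjoint, exhaustive train/test split of records.

    Stratifies on ``labels`` (default: record labels); if any class has a
    single sample the split falls back to unstratified with a warning.
    Deterministic per seed.
    """
    records = list(records)
    if len(records) < 5:
        raise ValueError("need at least 5 samples to split")
    if not 0 < test_fraction < 1:
        raise ValueError("test fraction must be in (0, 1)")
    y = np.array([r.label for r in records]) if labels is None \
        else np.asarray(labels)
    _, counts = np.unique(y, return_counts=True)
    strat = y
    if counts.min() < 2:
        warnings.warn("a class has a single sample; splitting without "
                      "stratification", RuntimeWarning, stacklevel=2)
        strat = None
    idx = np.arange(len(records))
    tr, te = train_test_split(idx, test_size=test_fraction,
                              random_state=seed, stratify=strat,
                              shuffle=True)
    return [records[i] for i in tr], [records[i] for i in te]


class FittedClassifier:
    """A trained classifier exposing aligned class-probability scores.

    SVM decision values are mapped through a logistic squash — a monotone
    map, so threshold-free metrics such as AUC are unaffected.
    """

    def __init__(self, kind: str, model, classes: np.ndarray,
                 n_features: int):
        self.kind = kind
        self._model = model
        self.classes_ = np.asarray(classes)
        self.n_features = int(n_features)

    def _check(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim != 2 or (x.shape[0] and x.shape[1] != self.n_features):
            raise ValueError(f"expected (n, {self.n_features}) features, "
                             f"got {x.shape}")
        return x

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        x = self._check(x)
        if x.shape[0] == 0:
            return np.zeros((0, self.classes_.size))
        if self.kind == "cnn":
            return self._model.predict_proba(x)
        if self.kind == "svm":
            d = self._model.decision_function(x)
            if d.ndim == 1:  # binary: squash to pseudo-probability
                p1 = 1.0 / (1.0 + np.exp(-d))
                return np.column_stack([1.0 - p1, p1])
            e = np.exp(d - d.max(axis=1, keepdims=True))
            return e / e.sum(axis=1, keepdims=True)
        return self._model.predict_proba(x)

    def predict(self, x: np.ndarray) -> np.ndarray:
        proba = self.predict_proba(x)
        if proba.shape[0] == 0:
            return np.array([], dtype=self.classes_.dtype)
        return self.classes_[np.argmax(proba, axis=1)]


def build_cnn(input_len: int, n_classes: int,
              seed: int = 42) -> ConvAttentionNet:
    """Untrained Conv–Attention–MLP classifier: two conv layers (64 and 256
    filters, kernels 5 and 3), channel + spatial attention, global max
    pooling, a residual MLP branch, and a fused softmax head."""
    return ConvAttentionNet(input_len, n_classes, loss="ce", seed=seed)


def _one_hot(y: np.ndarray, classes: np.ndarray) -> np.ndarray:
    out = np.zeros((y.size, classes.size))
    lut = {c: j for j, c in enumerate(classes)}
    for i, v in enumerate(y):
        out[i, lut[v]] = 1.0
    return out


def train_classifier(spec: ClassifierSpec, records, task: str,
                     features: np.ndarray | None = None) -> FittedClassifier:
    """Train one classifier on feature records for the given task.

    ``features`` overrides the records' own vectors (e.g. PCA/UMAP
    representations); labels always come from the records via the task
    mapping. Raises on a single-class training set.
    """
    records = list(records)
    x = np.vstack([r.vector for r in records]) if features is None \
        else np.asarray(features, dtype=float)
    y = task_labels(records, task)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training set contains a single class")

    if spec.kind == "rf":
        model = RandomForestClassifier(n_estimators=spec.n_estimators,
                                       random_state=spec.seed).fit(x, y)
    elif spec.kind == "svm":
        model = SVC(kernel="linear", class_weight="balanced",
                    random_state=spec.seed).fit(x, y)
    elif spec.kind == "lr":
        model = LogisticRegression(max_iter=2000,
                                   random_state=spec.seed).fit(x, y)
    elif spec.kind == "gbt":
        model = GradientBoostingClassifier(
            n_estimators=spec.n_estimators,
            learning_rate=spec.learning_rate, max_depth=spec.max_depth,
            random_state=spec.seed).fit(x, y)
    else:  # cnn
        net = build_cnn(x.shape[1], classes.size, seed=spec.seed)
        yh = _one_hot(y, classes)
        xt, xv, yt, yv = train_test_split(
            x, yh, test_size=0.2, random_state=spec.seed, stratify=y)
        net.fit(xt, yt, xv, yv, epochs=spec.epochs,
                batch_size=spec.batch_size, lr=spec.nn_lr,
                patience=spec.patience, seed=spec.seed)
        model = net
    fitted_classes = classes if spec.kind == "cnn" \
        else np.asarray(model.classes_)
    return FittedClassifier(spec.kind, model, fitted_classes, x.shape[1])


class FittedQuantifier:
    """A trained composition model predicting the five oil fractions."""

    def __init__(self, net: ConvAttentionNet):
        self._net = net
        self.oils = OIL_CLASSES
        self.n_features = net.input_len

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim != 2 or (x.shape[0] and x.shape[1] != self.n_features):
            raise ValueError(f"expected (n, {self.n_features}) features, "
                             f"got {x.shape}")
        if x.shape[0] == 0:
            return np.zeros((0, 5))
        return self._net.predict_proba(x)

    @property
    def history(self):
        return self._net.history


def train_quantifier(spec: QuantifierSpec, records,
                     features: np.ndarray | None = None) -> FittedQuantifier:
    """Train the Conv–Attention–MLP quantifier on composition-labelled
    records; a ``val_fraction`` slice of the training data drives early
    stopping, and the training curve is retained on the fitted model."""
    records = list(records)
    x = np.vstack([r.vector for r in records]) if features is None \
        else np.asarray(features, dtype=float)
    fr = np.vstack([r.fractions for r in records])
    if fr.shape[1] != 5 or np.any(fr < 0) or \
            np.any(np.abs(fr.sum(axis=1) - 1.0) > 1e-6):
        raise ValueError("records must carry 5 non-negative fractions "
                         "summing to 1")
    net = ConvAttentionNet(x.shape[1], 5, loss="mse", seed=spec.seed)
    xt, xv, yt, yv = train_test_split(x, fr, test_size=spec.val_fraction,
                                      random_state=spec.seed, shuffle=True)
    net.fit(xt, yt, xv, yv, epochs=spec.epochs, batch_size=spec.batch_size,
            lr=spec.lr, patience=spec.patience, seed=spec.seed)
    return FittedQuantifier(net)


def predict(model, features: np.ndarray) -> np.ndarray:
    """Per-sample class probabilities or fraction vectors, aligned to
    input order."""
    if isinstance(model, FittedQuantifier):
        return model.predict(features)
    if isinstance(model, FittedClassifier):
        return model.predict_proba(features)
    raise TypeError(f"unsupported model type {type(model).__name__}")
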