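"""Classifiers for the six-class emotion problem.

The probabilistic neural network (PNN), extreme learning machine (ELM) and
k-nearest-neighbour (KNN) classifiers are implemented here directly —
PNN/ELM because their exact scoring rules (Gaussian-kernel class densities
with bandwidth sigma; random hidden layer with ridge least-squares output
weights) are the quantities under study, KNN because its distance- and
vote-tie rules are fixed contractually (distance ties broken by training
index order, vote ties by lowest class index).  Decision trees and random
forests are standard CART/bagging and delegate to scikit-learn behind the
same fit/predict surface.

All classifiers expose ``fit(X, y)`` and ``predict(X)`` with ``classes_``
sorted; predictions are deterministic given the fitted state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from scipy.special import logsumexp
from sklearn.ensemble import RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "PNNClassifier",
    "ELMClassifier",
    "KNNClassifier",
    "TreeClassifier",
    "ForestClassifier",
    "make_classifier",
    "pnn_class_scores",
]


def _validate_xy(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y length mismatch")
    if X.shape[0] == 0:
        raise ValueError("empty training set")
    return X, y


def pnn_class_scores(train_X, train_y, test_X, sigma: float) -> tuple[np.ndarray, np.ndarray]:
    """Log-domain PNN class scores.

    For each test point and class c the score is the *mean* over class-c
    training points of ``exp(-||x - xi||^2 / (2 sigma^2))`` (equal class
    priors), accumulated with log-sum-exp for stability at small sigma.
    Returns ``(classes, log_scores)`` with ``log_scores`` of shape
    (n_test, n_classes).
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    train_X, train_y = _validate_xy(train_X, train_y)
    test_X = np.atleast_2d(np.asarray(test_X, dtype=float))
    classes = np.unique(train_y)
    d2 = cdist(test_X, train_X, metric="sqeuclidean")
    log_k = -d2 / (2.0 * sigma * sigma)
    scores = np.empty((test_X.shape[0], classes.size))
    for ci, c in enumerate(classes):
        mask = train_y == c
        if not mask.any():
            raise ValueError(f"class {c!r} has no training points")
        scores[:, ci] = logsumexp(log_k[:, mask], axis=1) - np.log(mask.sum())
    return classes, scores


@dataclass
class PNNClassifier:
    """Probabilistic neural network: Parzen-window class densities with a
    Gaussian kernel of bandwidth ``sigma``; argmax class score, ties to the
    lowest class index."""

    sigma: float = 0.1

    def fit(self, X, y):
        X, y = _validate_xy(X, y)
        self.train_X_, self.train_y_ = X, y
        self.classes_ = np.unique(y)
        for c in self.classes_:
            if (y == c).sum() < 1:
                raise ValueError(f"class {c!r} has no training points")
        return self

    def predict(self, X):
        classes, scores = pnn_class_scores(self.train_X_, self.train_y_, X, self.sigma)
        return classes[np.argmax(scores, axis=1)]  # argmax -> first (lowest) on ties


_ACTIVATIONS = {
    "sigmoid": lambda z: 1.0 / (1.0 + np.exp(-z)),
    "tanh": np.tanh,
    "hardlim": lambda z: (z >= 0).astype(float),
    "gaussian": lambda z: np.exp(-np.square(z)),
}


@dataclass
class ELMClassifier:
    """Extreme learning machine: a single random hidden layer with
    ridge-regularized least-squares output weights on one-hot targets.

    kernel="mlp": hidden weights and biases drawn uniform[-1, 1] from the
    seed, hidden output via the chosen activation.  kernel="rbf": hidden
    units are Gaussian bumps ``exp(-||x - c||^2 / (2 rbf_width^2))`` at
    centers drawn (seeded, with replacement if needed) from training rows.
    Deterministic given the seed; ridge ``lam`` keeps the normal equations
    nonsingular in the overparameterized regime.
    """

    kernel: str = "mlp"
    activation: str = "sigmoid"
    n_hidden: int = 100
    rbf_width: float = 1.0
    seed: int = 0
    lam: float = 1e-6

    def fit(self, X, y):
        if self.n_hidden < 1:
            raise ValueError("n_hidden must be >= 1")
        if self.kernel not in ("mlp", "rbf"):
            raise ValueError(f"unknown ELM kernel {self.kernel!r}")
        if self.kernel == "mlp" and self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")
        X, y = _validate_xy(X, y)
        self.classes_ = np.unique(y)
        targets = (y[:, None] == self.classes_[None, :]).astype(float)

        rng = np.random.default_rng(self.seed)
        if self.kernel == "mlp":
            self.W_ = rng.uniform(-1.0, 1.0, size=(X.shape[1], self.n_hidden))
            self.b_ = rng.uniform(-1.0, 1.0, size=self.n_hidden)
        else:
            idx = rng.choice(X.shape[0], size=self.n_hidden, replace=self.n_hidden > X.shape[0])
            self.centers_ = X[idx]
        H = self._hidden(X)
        A = H.T @ H + self.lam * np.eye(H.shape[1])
        self.beta_ = np.linalg.solve(A, H.T @ targets)
        return self

    def _hidden(self, X):
        if self.kernel == "mlp":
            return _ACTIVATIONS[self.activation](X @ self.W_ + self.b_)
        d2 = cdist(X, self.centers_, metric="sqeuclidean")
        return np.exp(-d2 / (2.0 * self.rbf_width**2))

    def predict(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = self._hidden(X) @ self.beta_
        return self.classes_[np.argmax(out, axis=1)]


@dataclass
class KNNClassifier:
    """k-nearest neighbours with selectable metric.

    Metrics: euclidean, manhattan, chebyshev, minkowski (order ``p``,
    default 3 so it is distinct from euclidean).  Neighbour ties at equal
    distance are resolved by training index order (stable sort); vote ties
    by the lowest class index.
    """

    k: int = 1
    metric: str = "euclidean"
    p: float = 3.0

    _METRICS = ("euclidean", "manhattan", "chebyshev", "minkowski")

    def fit(self, X, y):
        if self.metric not in self._METRICS:
            raise ValueError(
                f"unknown metric {self.metric!r}; choose from {self._METRICS}"
            )
        X, y = _validate_xy(X, y)
        if not 1 <= self.k <= X.shape[0]:
            raise ValueError(f"k={self.k} out of range for {X.shape[0]} training points")
        self.train_X_, self.train_y_ = X, y
        self.classes_ = np.unique(y)
        return self

    def _distances(self, X):
        if self.metric == "manhattan":
            return cdist(X, self.train_X_, metric="cityblock")
        if self.metric == "minkowski":
            return cdist(X, self.train_X_, metric="minkowski", p=self.p)
        return cdist(X, self.train_X_, metric=self.metric)

    def predict(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        d = self._distances(X)
        nn = np.argsort(d, axis=1, kind="stable")[:, : self.k]
        votes = self.train_y_[nn]
        out = np.empty(X.shape[0], dtype=self.train_y_.dtype)
        for i in range(X.shape[0]):
            counts = np.array([(votes[i] == c).sum() for c in self.classes_])
            out[i] = self.classes_[np.argmax(counts)]  # first max -> lowest class
        return out


@dataclass
class TreeClassifier:
    """Single CART decision tree (Gini impurity); deterministic given seed."""

    seed: int = 0

    def fit(self, X, y):
        X, y = _validate_xy(X, y)
        self.classes_ = np.unique(y)
        self._model = DecisionTreeClassifier(criterion="gini", random_state=self.seed)
        self._model.fit(X, y)
        return self

    def predict(self, X):
        return self._model.predict(np.atleast_2d(np.asarray(X, dtype=float)))


@dataclass
class ForestClassifier:
    """Random forest: bootstrap-resampled Gini CART trees with sqrt(D)
    feature subsampling and majority vote; deterministic given seed."""

    n_trees: int = 100
    seed: int = 0

    def fit(self, X, y):
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        X, y = _validate_xy(X, y)
        self.classes_ = np.unique(y)
        self._model = RandomForestClassifier(
            n_estimators=self.n_trees,
            criterion="gini",
            max_features="sqrt",
            bootstrap=True,
            random_state=self.seed,
        )
        self._model.fit(X, y)
        return self

    def predict(self, X):
        return self._model.predict(np.atleast_2d(np.asarray(X, dtype=float)))


_KINDS = {
    "pnn": PNNClassifier,
    "elm": ELMClassifier,
    "knn": KNNClassifier,
    "dt": TreeClassifier,
    "rf": ForestClassifier,
}


def make_classifier(kind: str, **hyperparams):
    """Instantiate a classifier by kind: pnn, elm, knn, dt or rf."""
    try:
        cls = _KINDS[kind.lower()]
    except KeyError:
        raise ValueError(f"unknown classifier kind {kind!r}; choose from {sorted(_KINDS)}")
    return cls(**hyperparams)
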