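"""Cross-validated evaluation and hyperparameter grid search.

Epochs are split with stratified 5-fold cross-validation (four folds
train, one tests, rotating).  Per configuration the report records the
per-class accuracies (recall per emotion), the overall mean accuracy with
its across-fold standard deviation, and macro one-vs-rest sensitivity and
specificity, all in percent.  Features are z-scored with statistics fit on
the training fold before classification, since the kernel-bandwidth grids
(PNN sigma up to 0.9, ELM RBF width up to 0.1) presuppose unit-scale
inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedKFold

from .classifiers import make_classifier

__all__ = [
    "stratified_kfold",
    "confusion_counts",
    "ClassMetrics",
    "class_metrics",
    "CVResult",
    "cross_validate",
    "CVReport",
    "grid_search",
    "published_grids",
]


def stratified_kfold(labels, k: int = 5, seed: int = 0) -> np.ndarray:
    """Assign each epoch to one of k disjoint folds, preserving class
    proportions within +-1 epoch; deterministic given the seed."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        small = classes[counts.argmin()]
        raise ValueError(
            f"class {small!r} has {counts.min()} epochs, fewer than k={k} folds"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = np.empty(labels.shape[0], dtype=int)
    for f, (_, test_idx) in enumerate(skf.split(np.zeros(labels.shape[0]), labels)):
        folds[test_idx] = f
    return folds


def confusion_counts(y_true, y_pred, classes) -> np.ndarray:
    """Confusion matrix with rows = true class, columns = predicted."""
    return _sk_confusion(y_true, y_pred, labels=list(classes))


@dataclass
class ClassMetrics:
    """Rates in percent derived from a confusion matrix."""

    classes: tuple
    per_class_accuracy: np.ndarray  # recall per class, %
    mean_accuracy: float            # total correct / total, %
    sensitivity: float              # macro one-vs-rest TP/(TP+FN), %
    specificity: float              # macro one-vs-rest TN/(TN+FP), %


def class_metrics(cm: np.ndarray, classes=None) -> ClassMetrics:
    """Per-class accuracy, overall accuracy and macro sensitivity/specificity.

    Per-class accuracy is the class recall ``cm[c,c] / row_sum(c)``; the
    macro averages are unweighted over classes.  Classes with no test
    epochs (empty row) are excluded from the macro averages with a warning.
    """
    cm = np.asarray(cm)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError(f"confusion matrix must be square, got {cm.shape}")
    n_cls = cm.shape[0]
    if classes is None:
        classes = tuple(range(n_cls))
    total = cm.sum()
    row = cm.sum(axis=1)
    col = cm.sum(axis=0)
    diag = np.diag(cm)

    present = row > 0
    if not present.all():
        warnings.warn("classes with no test epochs excluded from macro averages")
    per_class = np.full(n_cls, np.nan)
    per_class[present] = 100.0 * diag[present] / row[present]
    mean_acc = 100.0 * diag.sum() / total

    tp = diag.astype(float)
    fn = row - diag
    fp = col - diag
    tn = total - tp - fn - fp
    sens = 100.0 * np.mean(tp[present] / (tp[present] + fn[present]))
    spec_denom = tn + fp
    ok = present & (spec_denom > 0)
    spec = 100.0 * np.mean(tn[ok] / spec_denom[ok])
    return ClassMetrics(
        classes=tuple(classes),
        per_class_accuracy=per_class,
        mean_accuracy=float(mean_acc),
        sensitivity=float(sens),
        specificity=float(spec),
    )


@dataclass
class CVResult:
    """Outcome of one k-fold cross-validated run."""

    fold_accuracies: np.ndarray      # per-fold accuracy, %
    confusion: np.ndarray            # pooled over folds
    metrics: ClassMetrics

    @property
    def mean_accuracy(self) -> float:
        return float(self.metrics.mean_accuracy)

    @property
    def accuracy_std(self) -> float:
        return float(np.std(self.fold_accuracies, ddof=1))


def _zscore_fit(X):
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return mu, sd


def cross_validate(
    X,
    y,
    factory,
    k: int = 5,
    seed: int = 0,
    standardize: bool = True,
) -> CVResult:
    """Stratified k-fold CV of ``factory()`` (a zero-arg classifier builder).

    The classifier is refit on every training fold; standardization
    statistics are fit on the training fold only.  Pooled-confusion mean
    accuracy equals the total-correct fraction by construction.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    folds = stratified_kfold(y, k=k, seed=seed)
    classes = np.unique(y)
    cm = np.zeros((classes.size, classes.size), dtype=int)
    fold_acc = np.empty(k)
    for f in range(k):
        tr, te = folds != f, folds == f
        Xtr, Xte = X[tr], X[te]
        if standardize:
            mu, sd = _zscore_fit(Xtr)
            Xtr, Xte = (Xtr - mu) / sd, (Xte - mu) / sd
        clf = factory().fit(Xtr, y[tr])
        pred = clf.predict(Xte)
        cm += confusion_counts(y[te], pred, classes)
        fold_acc[f] = 100.0 * np.mean(pred == y[te])
    return CVResult(
        fold_accuracies=fold_acc,
        confusion=cm,
        metrics=class_metrics(cm, classes=tuple(classes)),
    )


def published_grids() -> dict[str, list[dict]]:
    """The published hyperparameter grids.

    PNN sigma 0.01..0.9 step 0.01; random-forest trees 20..600 step 20;
    ELM with MLP kernel over four activations and RBF kernel with width
    0.01..0.1 step 0.01, hidden neurons 1000..2500 step 100; KNN over four
    distance metrics (neighbour counts 1..9 odd; the source grid leaves k
    unstated); a single unparameterized decision tree.
    """
    sigmas = np.round(np.arange(0.01, 0.901, 0.01), 2)
    hidden = list(range(1000, 2501, 100))
    widths = np.round(np.arange(0.01, 0.101, 0.01), 2)
    grids: dict[str, list[dict]] = {
        "pnn": [{"sigma": float(s)} for s in sigmas],
        "rf": [{"n_trees": t} for t in range(20, 601, 20)],
        "dt": [{}],
        "knn": [
            {"k": k, "metric": m}
            for m in ("manhattan", "euclidean", "minkowski", "chebyshev")
            for k in (1, 3, 5, 7, 9)
        ],
        "elm": (
            [
                {"kernel": "mlp", "activation": a, "n_hidden": h}
                for a in ("sigmoid", "tanh", "hardlim", "gaussian")
                for h in hidden
            ]
            + [
                {"kernel": "rbf", "rbf_width": float(w), "n_hidden": h}
                for w in widths
                for h in hidden
            ]
        ),
    }
    return grids


@dataclass
class CVReport:
    """Grid-search outcome: one record per evaluated cell plus the best
    cell per classifier (ties to the earlier grid entry / feature set)."""

    records: pd.DataFrame
    best: dict[str, dict] = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)

    def best_row(self, kind: str) -> dict:
        return self.best[kind]


def grid_search(
    table: pd.DataFrame,
    grids: dict[str, list[dict]],
    feature_sets: list[tuple[str, list[str]]] | None = None,
    label_col: str = "label",
    k: int = 5,
    seed: int = 0,
    standardize: bool = True,
) -> CVReport:
    """Cross-validate every (feature set, classifier, hyperparameters) cell.

    ``feature_sets`` defaults to every individual ``sb<j>_<feature>``
    column (the one-feature-per-subband layout of the study's result
    tables); pass e.g. ``[("top6", cols)]`` to evaluate a joint feature
    vector.  Infeasible cells (such as k exceeding the training-fold size)
    are skipped with a warning.  The best cell per classifier maximizes
    mean accuracy; ties keep the earliest cell in iteration order, i.e.
    the smaller hyperparameter and lower subband.
    """
    if label_col not in table:
        raise ValueError(f"table has no {label_col!r} column")
    if not grids:
        raise ValueError("empty hyperparameter grids")
    y = table[label_col].to_numpy()
    if feature_sets is None:
        cols = [c for c in table.columns if c.startswith(("sb", "ch")) and "_" in c]
        feature_sets = [(c, [c]) for c in cols]

    classes = np.unique(y)
    recs = []
    best: dict[str, dict] = {}
    for fs_name, fs_cols in feature_sets:
        X = table[fs_cols].to_numpy(dtype=float)
        for kind, param_list in grids.items():
            for params in param_list:
                hp = dict(params)
                if kind in ("elm", "dt", "rf") and "seed" not in hp:
                    hp["seed"] = seed
                try:
                    res = cross_validate(
                        X, y, lambda: make_classifier(kind, **hp),
                        k=k, seed=seed, standardize=standardize,
                    )
                except ValueError as exc:
                    warnings.warn(f"skipping {kind} {params} on {fs_name}: {exc}")
                    continue
                rec = {
                    "classifier": kind,
                    "params": repr(params),
                    "feature_set": fs_name,
                    "acc_mean": res.mean_accuracy,
                    "acc_std": res.accuracy_std,
                    "sensitivity": res.metrics.sensitivity,
                    "specificity": res.metrics.specificity,
                }
                for c, a in zip(classes, res.metrics.per_class_accuracy):
                    rec[f"acc_{c}"] = a
                recs.append(rec)
                if kind not in best or rec["acc_mean"] > best[kind]["acc_mean"]:
                    best[kind] = {**rec, "result": res}
    return CVReport(records=pd.DataFrame(recs), best=best)
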