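"""End-to-end pipeline: decomposition -> features -> selection -> CV.

`run_pipeline` ties the stages together for a labelled EpochSet: every
channel of every epoch is decomposed with the chosen (Q, r, J), the eleven
features are computed per subband and averaged over channels, the six most
class-discriminant features are picked by one-way ANOVA (each at its best
subband) and the resulting feature vector is classified with a
hyperparameter grid under stratified 5-fold cross-validation.

By default feature selection is performed once on the full table before
cross-validation (the order the study reports, which leaks label
information into the selection stage); ``honest_selection=True`` refits
the ANOVA ranking inside every training fold instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classifiers import make_classifier
from .evaluation import (
    CVResult,
    class_metrics,
    confusion_counts,
    cross_validate,
    grid_search,
    stratified_kfold,
    CVReport,
)
from .features import FeatureConfig, extract_features
from .selection import ANOVARanking, rank_and_select, selected_columns
from .tqwt import TQWTParams

__all__ = ["PipelineResult", "run_pipeline", "cross_validate_honest"]


@dataclass
class PipelineResult:
    """Everything the pipeline produced, stage by stage."""

    feature_table: pd.DataFrame
    ranking: ANOVARanking
    selected_columns: list[str]
    report: CVReport
    best_classifier: str
    best_result: CVResult

    @property
    def mean_accuracy(self) -> float:
        return self.best_result.mean_accuracy


def cross_validate_honest(
    table: pd.DataFrame,
    factory,
    n_select: int = 6,
    label_col: str = "label",
    k: int = 5,
    seed: int = 0,
    standardize: bool = True,
) -> CVResult:
    """k-fold CV with the ANOVA selection refit inside each training fold.

    Guards against selection leakage: the test fold plays no part in
    choosing which features the classifier sees.
    """
    y = table[label_col].to_numpy()
    folds = stratified_kfold(y, k=k, seed=seed)
    classes = np.unique(y)
    cm = np.zeros((classes.size, classes.size), dtype=int)
    fold_acc = np.empty(k)
    for f in range(k):
        tr = folds != f
        ranking = rank_and_select(table.loc[tr], k=n_select, label_col=label_col)
        cols = selected_columns(ranking)
        Xtr = table.loc[tr, cols].to_numpy(dtype=float)
        Xte = table.loc[~tr, cols].to_numpy(dtype=float)
        if standardize:
            mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0)
            sd[sd == 0] = 1.0
            Xtr, Xte = (Xtr - mu) / sd, (Xte - mu) / sd
        clf = factory().fit(Xtr, y[tr])
        pred = clf.predict(Xte)
        cm += confusion_counts(y[~tr], pred, classes)
        fold_acc[f] = 100.0 * np.mean(pred == y[~tr])
    return CVResult(
        fold_accuracies=fold_acc,
        confusion=cm,
        metrics=class_metrics(cm, classes=tuple(classes)),
    )


def run_pipeline(
    epochs,
    Q: float = 1.0,
    r: float = 3.0,
    J: int = 8,
    grids: dict[str, list[dict]] | None = None,
    feature_cfg: FeatureConfig | None = None,
    n_select: int = 6,
    k: int = 5,
    seed: int = 0,
    honest_selection: bool = False,
    feature_table: pd.DataFrame | None = None,
) -> PipelineResult:
    """Run decomposition, feature extraction, selection and CV grid search.

    ``grids`` maps classifier kinds to hyperparameter lists (default: the
    PNN sigma grid 0.01..0.9 step 0.01).  A precomputed ``feature_table``
    skips the extraction stage.  Returns the per-stage artifacts and the
    best cross-validated configuration.
    """
    if grids is None:
        grids = {"pnn": [{"sigma": round(0.01 * i, 2)} for i in range(1, 91)]}
    if feature_table is None:
        params = TQWTParams(Q=Q, r=r, J=J)
        feature_table = extract_features(
            epochs, params, cfg=feature_cfg or FeatureConfig()
        )
    ranking = rank_and_select(feature_table, k=n_select)
    cols = selected_columns(ranking)

    if honest_selection:
        # per-fold selection is classifier independent: compute the fold
        # splits and selected/standardized features once, then grid over them
        y = feature_table["label"].to_numpy()
        folds = stratified_kfold(y, k=k, seed=seed)
        classes = np.unique(y)
        fold_data = []
        for f in range(k):
            tr = folds != f
            fold_rank = rank_and_select(feature_table.loc[tr], k=n_select)
            fcols = selected_columns(fold_rank)
            Xtr = feature_table.loc[tr, fcols].to_numpy(dtype=float)
            Xte = feature_table.loc[~tr, fcols].to_numpy(dtype=float)
            mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0)
            sd[sd == 0] = 1.0
            fold_data.append(((Xtr - mu) / sd, y[tr], (Xte - mu) / sd, y[~tr]))

        recs, best = [], {}
        for kind, param_list in grids.items():
            for params_ in param_list:
                hp = dict(params_)
                if kind in ("elm", "dt", "rf") and "seed" not in hp:
                    hp["seed"] = seed
                cm = np.zeros((classes.size, classes.size), dtype=int)
                fold_acc = np.empty(k)
                for f, (Xtr, ytr, Xte, yte) in enumerate(fold_data):
                    clf = make_classifier(kind, **hp).fit(Xtr, ytr)
                    pred = clf.predict(Xte)
                    cm += confusion_counts(yte, pred, classes)
                    fold_acc[f] = 100.0 * np.mean(pred == yte)
                res = CVResult(
                    fold_accuracies=fold_acc,
                    confusion=cm,
                    metrics=class_metrics(cm, classes=tuple(classes)),
                )
                rec = {
                    "classifier": kind,
                    "params": repr(params_),
                    "feature_set": "honest-top%d" % n_select,
                    "acc_mean": res.mean_accuracy,
                    "acc_std": res.accuracy_std,
                    "sensitivity": res.metrics.sensitivity,
                    "specificity": res.metrics.specificity,
                }
                recs.append(rec)
                if kind not in best or rec["acc_mean"] > best[kind]["acc_mean"]:
                    best[kind] = {**rec, "result": res}
        report = CVReport(records=pd.DataFrame(recs), best=best)
    else:
        report = grid_search(
            feature_table,
            grids,
            feature_sets=[(f"top{n_select}", cols)],
            k=k,
            seed=seed,
        )

    best_kind = max(report.best, key=lambda kk: report.best[kk]["acc_mean"])
    return PipelineResult(
        feature_table=feature_table,
        ranking=ranking,
        selected_columns=cols,
        report=report,
        best_classifier=best_kind,
        best_result=report.best[best_kind]["result"],
    )
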