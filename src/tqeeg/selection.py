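"""ANOVA-based feature ranking and selection.

Each (subband, feature) column of a feature table is scored with a one-way
ANOVA F test across the emotion classes.  A feature *name* (e.g. ``apen``)
is then ranked by the minimum p value it attains over subbands — i.e. by
its best subband — and the top-k names are selected (k=6 by default,
matching the six-feature working set: power, energy, approximate entropy,
fuzzy entropy, Tsallis entropy and variance are the kind of features this
stage is meant to surface when class band powers differ).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ANOVARanking", "anova_f", "rank_and_select", "selected_columns"]


def anova_f(values_by_class) -> tuple[float, float]:
    """Classic one-way ANOVA F statistic and upper-tail p value.

    ``F = MS_between / MS_within`` with (g-1, n-g) degrees of freedom.
    Zero within-group variance with unequal group means returns the
    ``(+inf, 0.0)`` sentinel.
    """
    groups = [np.asarray(g, dtype=float).ravel() for g in values_by_class]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("every group needs at least two observations")
    ssw = sum(float(np.sum((g - g.mean()) ** 2)) for g in groups)
    means = [g.mean() for g in groups]
    if ssw == 0.0 and len(set(np.round(means, 12))) > 1:
        return float("inf"), 0.0
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


@dataclass
class ANOVARanking:
    """Per-column ANOVA scores plus the ranked/selected feature names.

    ``scores`` has one row per (subband, feature) column with columns
    ``feature, subband, column, F, p``.  ``ranking`` aggregates to one row
    per feature name (minimum p over subbands, its F and best subband) in
    rank order; ``selected`` is the top-k feature-name tuple.
    """

    scores: pd.DataFrame
    ranking: pd.DataFrame
    selected: tuple[str, ...]

    def to_csv(self, path) -> None:
        out = self.scores.copy()
        out["rank"] = out["feature"].map(
            {f: i + 1 for i, f in enumerate(self.ranking["feature"])}
        )
        out["selected"] = out["feature"].isin(self.selected)
        out.to_csv(path, index=False)


_COL_RE = re.compile(r"^(?:ch(?P<ch>\d+)_)?sb(?P<sb>\d+)_(?P<feat>\w+)$")


def _parse_columns(columns) -> pd.DataFrame:
    rows = []
    for col in columns:
        m = _COL_RE.match(col)
        if m:
            rows.append((col, int(m.group("sb")), m.group("feat")))
    if not rows:
        raise ValueError("no 'sb<j>_<feature>' columns found in table")
    return pd.DataFrame(rows, columns=["column", "subband", "feature"])


def rank_and_select(table: pd.DataFrame, k: int = 6, label_col: str = "label") -> ANOVARanking:
    """Rank feature names by one-way ANOVA across classes; select the top k.

    Every ``sb<j>_<feature>`` column is tested individually; a feature name
    is scored by its best (minimum-p) subband.  Ties are broken by higher
    F, then lexicographic name, so the ranking is deterministic.
    """
    if label_col not in table:
        raise ValueError(f"table has no {label_col!r} column")
    cols = _parse_columns([c for c in table.columns if c not in (label_col, "group")])
    n_features = cols["feature"].nunique()
    if k > n_features:
        raise ValueError(f"k={k} exceeds the {n_features} distinct feature names")

    labels = table[label_col].to_numpy()
    classes = np.unique(labels)
    stats_rows = []
    for col in cols["column"]:
        groups = [table.loc[labels == c, col].to_numpy() for c in classes]
        f, p = anova_f(groups)
        stats_rows.append((f, p))
    scores = cols.copy()
    scores[["F", "p"]] = np.asarray(stats_rows)

    best = (
        scores.sort_values(["p", "F", "column"], ascending=[True, False, True])
        .groupby("feature", as_index=False)
        .first()
    )
    ranking = best.sort_values(
        ["p", "F", "feature"], ascending=[True, False, True]
    ).reset_index(drop=True)
    selected = tuple(ranking["feature"].head(k))
    return ANOVARanking(scores=scores, ranking=ranking, selected=selected)


def selected_columns(ranking: ANOVARanking) -> list[str]:
    """Table columns of the selected features at their best subbands."""
    sel = ranking.ranking.set_index("feature").loc[list(ranking.selected)]
    return list(sel["column"])
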