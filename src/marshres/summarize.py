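"""Aggregation of unit-level scores to arbitrary grouping scales:
mean +/- SD per category and total, management-category contingency tables,
and the best / worst metric per group.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .management import ALL_KEYS
from .scoring import METRICS

__all__ = [
    "group_summary",
    "extreme_metrics",
    "category_count_table",
    "pooled_mean",
]

_SCORE_COLUMNS = ("score_condition", "score_vulnerability", "score_adaptive", "total_score")


def group_summary(
    scores: pd.DataFrame, grouping_label: str | None = None, ddof: int = 1
) -> pd.DataFrame:
    """Per-group n, mean and SD of every category/total score, management-key
    counts, and the extreme metrics.

    ``ddof=1`` gives the sample standard deviation; missing scores are
    excluded per column.  A missing ``grouping_label`` pools everything into
    a single "all" group.
    """
    df = scores.copy()
    if grouping_label is None or grouping_label not in df.columns:
        if grouping_label is not None:
            warnings.warn(f"grouping label {grouping_label!r} absent; using single group")
        df["_group"] = "all"
        grouping_label = "_group"
    rows = []
    for group, sub in df.groupby(grouping_label, sort=True):
        if len(sub) == 0:
            warnings.warn(f"group {group!r} is empty; omitted")
            continue
        row: dict[str, object] = {"group": group, "n_units": len(sub)}
        for col in _SCORE_COLUMNS:
            vals = sub[col].astype(float).dropna()
            row[f"mean_{col}"] = vals.mean() if len(vals) else np.nan
            row[f"sd_{col}"] = vals.std(ddof=ddof) if len(vals) > ddof else (0.0 if len(vals) else np.nan)
        if "management_key" in sub.columns:
            counts = sub["management_key"].value_counts()
            for key in ALL_KEYS:
                row[f"count_{key}"] = int(counts.get(key, 0))
        top_pos, top_neg = extreme_metrics(sub)
        row["top_positive_metric"] = top_pos
        row["top_negative_metric"] = top_neg
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")


def extreme_metrics(scores: pd.DataFrame) -> tuple[str, str]:
    """(best, worst) metric by group-mean signed metric score.

    Ties break toward the first metric in canonical order.
    """
    means = {}
    for m in METRICS:
        col = scores[f"metric_score_{m}"].astype(float).dropna()
        means[m] = col.mean() if len(col) else -np.inf
    best = max(METRICS, key=lambda m: (means[m], -METRICS.index(m)))
    worst = min(METRICS, key=lambda m: (means[m], METRICS.index(m)))
    return best, worst


def category_count_table(
    keys: pd.Series, groups: pd.Series | None = None
) -> pd.DataFrame:
    """Contingency table of management keys by group, with Total row and
    column.  Unclassified units (missing key) are excluded; the grand total
    therefore equals the number of classified units."""
    df = pd.DataFrame({"key": keys})
    df["group"] = groups if groups is not None else "all"
    df = df.dropna(subset=["key"])
    table = pd.crosstab(df["key"], df["group"]).reindex(list(ALL_KEYS), fill_value=0)
    table.index.name = "management_key"
    table["Total"] = table.sum(axis=1)
    table.loc["Total"] = table.sum(axis=0)
    return table


def pooled_mean(means, ns) -> float:
    """Size-weighted pooled mean of subgroup means."""
    means = np.asarray(means, dtype=float)
    ns = np.asarray(ns, dtype=float)
    if means.shape != ns.shape or ns.sum() <= 0:
        raise ValueError("means and ns must align, with positive total n")
    return float(np.sum(means * ns) / np.sum(ns))
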