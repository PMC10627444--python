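"""Decile-rank scoring: metric ranks, signed scores, weighted category sums,
category scores and the total resilience score.

Conventions, stated once and used everywhere:

* Decile breaks are the 10th..90th percentiles under the linear-interpolation
  ("type 7") quantile definition.
* A value equal to a break falls in the lower bin: rank = 1 + #{breaks < v}.
  With heavily tied data duplicate breaks legitimately leave bins empty.
* Metrics with a negative influence are multiplied by -1 after ranking.
* Category sums weight hardened shoreline 1.5x and migration space 2x; all
  other metrics weigh 1.
* Condition and adaptive category scores rank the sums into 1..10 ascending.
  Vulnerability ranks the *negated* sums (most vulnerable unit ranks 10) and
  then multiplies by -1, giving a -1 (least) .. -10 (most vulnerable) scale.
* Total score: decile rank of condition + vulnerability + adaptive.
* A unit missing any metric of a category gets a missing category score and
  is excluded from that category's decile computation; scoring a cohort of
  fewer than two units is refused (ranks are relative by construction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CONDITION_METRICS",
    "VULNERABILITY_METRICS",
    "ADAPTIVE_METRICS",
    "METRICS",
    "CATEGORIES",
    "MetricDirections",
    "decile_breaks",
    "rank_value",
    "rank_values",
    "score_metrics",
    "category_sum",
    "category_score",
    "total_score",
    "score_table",
]

CONDITION_METRICS = (
    "area_to_edge_ratio",
    "unveg_edge_ratio",
    "pct_impervious",
    "pct_natural",
    "pct_agricultural",
)
VULNERABILITY_METRICS = (
    "soil_erodibility",
    "tidal_range_m",
    "pct_below_mhhw",
    "pct_below_mtl",
)
ADAPTIVE_METRICS = (
    "pct_hardened",
    "shoreline_complexity",
    "migration_ratio",
    "connectedness",
)
METRICS = CONDITION_METRICS + VULNERABILITY_METRICS + ADAPTIVE_METRICS
CATEGORIES: dict[str, tuple[str, ...]] = {
    "condition": CONDITION_METRICS,
    "vulnerability": VULNERABILITY_METRICS,
    "adaptive": ADAPTIVE_METRICS,
}

_DEFAULT_SIGNS = {
    "area_to_edge_ratio": +1,
    "unveg_edge_ratio": -1,
    "pct_impervious": -1,
    "pct_natural": +1,
    "pct_agricultural": -1,
    "soil_erodibility": -1,
    "tidal_range_m": +1,
    "pct_below_mhhw": -1,
    "pct_below_mtl": -1,
    "pct_hardened": -1,
    "shoreline_complexity": +1,
    "migration_ratio": +1,
    "connectedness": +1,
}
_DEFAULT_WEIGHTS = {m: 1.0 for m in METRICS}
_DEFAULT_WEIGHTS["pct_hardened"] = 1.5
_DEFAULT_WEIGHTS["migration_ratio"] = 2.0


@dataclass
class MetricDirections:
    """Per-metric influence sign (+1/-1) and summation weight."""

    signs: dict[str, int] = field(default_factory=lambda: dict(_DEFAULT_SIGNS))
    weights: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_WEIGHTS))

    def __post_init__(self) -> None:
        for m, s in self.signs.items():
            if s not in (+1, -1):
                raise ValueError(f"sign for {m} must be +1 or -1")
        for m, w in self.weights.items():
            if w <= 0:
                raise ValueError(f"weight for {m} must be positive")


def decile_breaks(values) -> np.ndarray:
    """Nine ascending break values (10th..90th percentile, linear
    interpolation).  Missing values are ignored; all-missing is an error."""
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise ValueError("decile_breaks needs at least one non-missing value")
    return np.quantile(arr, np.arange(1, 10) / 10.0)


def rank_value(v: float, breaks: np.ndarray) -> float:
    """Bin rank 1..10: one plus the number of breaks strictly below v.
    Values tied with a break fall in the lower bin."""
    if not np.isfinite(v):
        return float("nan")
    return float(1 + np.count_nonzero(np.asarray(breaks) < v))


def rank_values(values, breaks: np.ndarray) -> np.ndarray:
    """Vectorized :func:`rank_value` (NaN propagates)."""
    arr = np.asarray(values, dtype=float)
    br = np.sort(np.asarray(breaks, dtype=float))
    out = (1 + np.searchsorted(br, arr, side="left")).astype(float)
    out[~np.isfinite(arr)] = np.nan
    return out


def score_metrics(table: pd.DataFrame, dirs: MetricDirections | None = None) -> pd.DataFrame:
    """Per-metric decile ranks and signed scores over the whole cohort.

    Returns a frame indexed like ``table`` with ``metric_rank_<m>`` and
    ``metric_score_<m>`` columns.
    """
    dirs = dirs or MetricDirections()
    if len(table) < 2:
        raise ValueError("relative scoring needs a cohort of at least 2 units")
    missing = [m for m in METRICS if m not in table.columns]
    if missing:
        raise ValueError(f"metric table lacks columns: {missing}")
    out = pd.DataFrame(index=table.index)
    for m in METRICS:
        col = table[m].astype(float)
        if np.isfinite(col).any():
            ranks = rank_values(col.to_numpy(), decile_breaks(col))
        else:
            ranks = np.full(len(col), np.nan)
        out[f"metric_rank_{m}"] = ranks
        out[f"metric_score_{m}"] = dirs.signs[m] * ranks
    return out


def category_sum(
    scores: pd.DataFrame, category: str, dirs: MetricDirections | None = None
) -> pd.Series:
    """Weighted sum of signed metric scores for one category; NaN when any
    member metric is missing."""
    dirs = dirs or MetricDirections()
    metrics = CATEGORIES[category]
    total = pd.Series(0.0, index=scores.index)
    for m in metrics:
        total = total + dirs.weights[m] * scores[f"metric_score_{m}"].astype(float)
    return total


def category_score(sums: pd.Series, category: str) -> pd.Series:
    """Decile rank of the category sums.

    Condition/adaptive: 1..10 ascending in the sum.  Vulnerability: the
    negated sums are ranked ascending (most vulnerable ranks 10) and the
    rank is negated, yielding -1 (least) .. -10 (most vulnerable).
    """
    vals = sums.astype(float)
    ok = np.isfinite(vals)
    if ok.sum() < 2:
        raise ValueError("category scoring needs at least 2 units with complete sums")
    out = pd.Series(np.nan, index=sums.index)
    if category == "vulnerability":
        neg = -vals[ok]
        out[ok] = -rank_values(neg.to_numpy(), decile_breaks(neg))
    else:
        out[ok] = rank_values(vals[ok].to_numpy(), decile_breaks(vals[ok]))
    return out


def total_score(cat_scores: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """(total_sum, total_score): sum the three category scores (vulnerability
    already negative) and decile-rank the sums into 1..10."""
    total_sum = (
        cat_scores["score_condition"].astype(float)
        + cat_scores["score_vulnerability"].astype(float)
        + cat_scores["score_adaptive"].astype(float)
    )
    ok = np.isfinite(total_sum)
    if ok.sum() < 2:
        raise ValueError("total scoring needs at least 2 units with all categories")
    ts = pd.Series(np.nan, index=total_sum.index)
    ts[ok] = rank_values(total_sum[ok].to_numpy(), decile_breaks(total_sum[ok]))
    return total_sum, ts


def score_table(table: pd.DataFrame, dirs: MetricDirections | None = None) -> pd.DataFrame:
    """Full pipeline: metric ranks/scores, category sums/scores, totals.

    ``table`` is a raw metric table indexed by unit_id with the 13 canonical
    metric columns; extra columns (group labels) are carried through.
    """
    dirs = dirs or MetricDirections()
    scores = score_metrics(table, dirs)
    for cat in CATEGORIES:
        scores[f"sum_{cat}"] = category_sum(scores, cat, dirs)
    for cat in CATEGORIES:
        scores[f"score_{cat}"] = category_score(scores[f"sum_{cat}"], cat)
    scores["total_sum"], scores["total_score"] = total_score(scores)
    extras = [c for c in table.columns if c not in METRICS]
    for c in extras:
        scores[c] = table[c]
    return scores
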