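"""Ordinal High/Low classification and the eight management categories.

Category scores at or beyond the threshold are "High": condition >= 6,
adaptive >= 6, vulnerability <= -6 (its scale is negative).  The key string
concatenates the three ordinals in condition-vulnerability-adaptive order,
e.g. ``"High-Low-High"``.
"""

from __future__ import annotations

import itertools
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ALL_KEYS",
    "DEFAULT_RECOMMENDATIONS",
    "ordinal_classify",
    "classify_table",
    "RecommendationTable",
    "recommend",
]

ALL_KEYS = tuple(
    f"{c}-{v}-{a}"
    for c, v, a in itertools.product(("High", "Low"), repeat=3)
)

#: Action lists are data, not code.  The two characterized combinations ship
#: with real defaults; the other six carry explicit placeholders that users
#: are expected to replace with their own elicitation results.
DEFAULT_RECOMMENDATIONS: dict[str, list[str]] = {
    "High-Low-High": [
        "maintain current marsh extent through conservation actions",
        "prioritize acquisition/protection of adjacent migration space",
    ],
    "Low-High-Low": [
        "limit protection of existing vegetation; prioritize major restoration",
        "remove barriers to migration",
        "consider experimental restoration methods (e.g. thin layer placement)",
    ],
}
for _key in ALL_KEYS:
    DEFAULT_RECOMMENDATIONS.setdefault(
        _key, [f"PLACEHOLDER: supply site-specific actions for {_key}"]
    )


def ordinal_classify(condition: float, vulnerability: float, adaptive: float) -> str | None:
    """Map a (condition, vulnerability, adaptive) score triple to its
    management key; returns None when any score is missing."""
    vals = (condition, vulnerability, adaptive)
    if any(v is None or not np.isfinite(v) for v in vals):
        return None
    c = "High" if condition >= 6 else "Low"
    v = "High" if vulnerability <= -6 else "Low"
    a = "High" if adaptive >= 6 else "Low"
    return f"{c}-{v}-{a}"


def classify_table(scores: pd.DataFrame) -> pd.Series:
    """management_key column for a ScoreTable frame (NaN-safe)."""
    return pd.Series(
        [
            ordinal_classify(c, v, a)
            for c, v, a in zip(
                scores["score_condition"],
                scores["score_vulnerability"],
                scores["score_adaptive"],
            )
        ],
        index=scores.index,
        name="management_key",
    )


class RecommendationTable:
    """Complete map from the eight management keys to ordered action lists."""

    def __init__(self, actions: Mapping[str, list[str]]):
        missing = set(ALL_KEYS) - set(actions)
        if missing:
            raise ValueError(f"recommendation table incomplete; missing keys: {sorted(missing)}")
        self.actions = {k: list(actions[k]) for k in ALL_KEYS}

    @classmethod
    def default(cls) -> "RecommendationTable":
        return cls(DEFAULT_RECOMMENDATIONS)

    @classmethod
    def from_yaml(cls, path) -> "RecommendationTable":
        with open(path) as fh:
            return cls(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.actions, fh, sort_keys=True)


def recommend(key: str, table: RecommendationTable | None = None) -> list[str]:
    """Ordered action list for one management key."""
    table = table or RecommendationTable.default()
    if key not in table.actions:
        raise KeyError(f"unknown management key: {key!r}")
    return list(table.actions[key])
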