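"""Independent brute-force reimplementations used as test oracles.

Deliberately written with plain Python loops and explicit formulas, without
importing any computation from the package under test, so the two routes
stay independent.
"""

from __future__ import annotations

import math
from collections import deque

SIGNS = {
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
WEIGHTS = {m: 1.0 for m in SIGNS}
WEIGHTS["pct_hardened"] = 1.5
WEIGHTS["migration_ratio"] = 2.0
CATS = {
    "condition": [
        "area_to_edge_ratio", "unveg_edge_ratio", "pct_impervious",
        "pct_natural", "pct_agricultural",
    ],
    "vulnerability": [
        "soil_erodibility", "tidal_range_m", "pct_below_mhhw", "pct_below_mtl",
    ],
    "adaptive": [
        "pct_hardened", "shoreline_complexity", "migration_ratio", "connectedness",
    ],
}


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def quantile_type7(values: list[float], q: float) -> float:
    xs = sorted(values)
    h = (len(xs) - 1) * q
    f = math.floor(h)
    if f + 1 >= len(xs):
        return xs[-1]
    return xs[f] + (h - f) * (xs[f + 1] - xs[f])


def decile_breaks(values: list[float]) -> list[float]:
    return [quantile_type7(values, i / 10.0) for i in range(1, 10)]


def rank(v: float, breaks: list[float]) -> int:
    r = 1
    for b in breaks:
        if b < v:
            r += 1
    return r


def score_cohort(rows: dict[str, dict[str, float]]) -> dict[str, dict[str, float]]:
    """Full scoring pipeline by brute force.

    rows: unit_id -> {metric: value}.  Returns unit_id -> flat dict with
    rank_<m>, score_<m>, sum_<cat>, score_<cat>, total_sum, total_score.
    """
    units = list(rows)
    out: dict[str, dict[str, float]] = {u: {} for u in units}
    for metric in SIGNS:
        vals = [rows[u][metric] for u in units]
        breaks = decile_breaks(vals)
        for u in units:
            r = rank(rows[u][metric], breaks)
            out[u][f"rank_{metric}"] = r
            out[u][f"score_{metric}"] = SIGNS[metric] * r
    for cat, metrics in CATS.items():
        for u in units:
            out[u][f"sum_{cat}"] = sum(
                WEIGHTS[m] * out[u][f"score_{m}"] for m in metrics
            )
        sums = [out[u][f"sum_{cat}"] for u in units]
        if cat == "vulnerability":
            breaks = decile_breaks([-s for s in sums])
            for u in units:
                out[u][f"score_{cat}"] = -rank(-out[u][f"sum_{cat}"], breaks)
        else:
            breaks = decile_breaks(sums)
            for u in units:
                out[u][f"score_{cat}"] = rank(out[u][f"sum_{cat}"], breaks)
    for u in units:
        out[u]["total_sum"] = (
            out[u]["score_condition"]
            + out[u]["score_vulnerability"]
            + out[u]["score_adaptive"]
        )
    totals = [out[u]["total_sum"] for u in units]
    breaks = decile_breaks(totals)
    for u in units:
        out[u]["total_score"] = rank(out[u]["total_sum"], breaks)
    return out


def ordinal_key(c: float, v: float, a: float) -> str:
    return "-".join(
        [
            "High" if c >= 6 else "Low",
            "High" if v <= -6 else "Low",
            "High" if a >= 6 else "Low",
        ]
    )


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def core_edge_counts(marsh, vegetated, valid, mask, connectivity=4):
    """(n_core, n_edge, n_unveg_edge) by explicit neighbour loops.

    All arguments are 2-D nested lists / arrays of booleans.
    """
    rows, cols = len(marsh), len(marsh[0])
    offs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if connectivity == 8:
        offs += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    n_core = n_edge = n_unveg = 0
    for r in range(rows):
        for c in range(cols):
            if not (marsh[r][c] and valid[r][c] and mask[r][c]):
                continue
            is_edge = unveg = False
            for dr, dc in offs:
                rr, cc = r + dr, c + dc
                if not (0 <= rr < rows and 0 <= cc < cols):
                    continue
                if valid[rr][cc] and not marsh[rr][cc]:
                    is_edge = True
                    if not vegetated[rr][cc]:
                        unveg = True
            if is_edge:
                n_edge += 1
                if unveg:
                    n_unveg += 1
            else:
                n_core += 1
    return n_core, n_edge, n_unveg


def flood_fill_candidates(marsh, water, migratable, elev, mhhw, depth):
    """BFS flood-fill version of the migration-space rule; returns a set of
    (row, col) candidate cells."""
    rows, cols = len(marsh), len(marsh[0])

    def passable(r, c):
        return water[r][c] or marsh[r][c] or elev[r][c] < mhhw[r][c] + depth

    seen = [[False] * cols for _ in range(rows)]
    queue = deque()
    for r in range(rows):
        for c in range(cols):
            if (marsh[r][c] or water[r][c]) and not seen[r][c]:
                seen[r][c] = True
                queue.append((r, c))
    while queue:
        r, c = queue.popleft()
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < rows and 0 <= cc < cols and not seen[rr][cc] and passable(rr, cc):
                seen[rr][cc] = True
                queue.append((rr, cc))
    out = set()
    for r in range(rows):
        for c in range(cols):
            if (
                seen[r][c]
                and migratable[r][c]
                and not marsh[r][c]
                and mhhw[r][c] <= elev[r][c] < mhhw[r][c] + depth
            ):
                out.add((r, c))
    return out


class UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        self.parent[self.find(a)] = self.find(b)


def group_units_by_marsh(marsh, unit_of_cell):
    """Union-find grouping of units sharing 4-connected marsh components.

    unit_of_cell: 2-D array of unit ids (or None).  Returns list of
    frozensets of unit ids.
    """
    rows, cols = len(marsh), len(marsh[0])
    cells = [(r, c) for r in range(rows) for c in range(cols) if marsh[r][c]]
    uf = UnionFind(cells)
    for r, c in cells:
        for dr, dc in ((1, 0), (0, 1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < rows and 0 <= cc < cols and marsh[rr][cc]:
                uf.union((r, c), (rr, cc))
    comp_units: dict = {}
    for r, c in cells:
        uid = unit_of_cell[r][c]
        if uid is not None:
            comp_units.setdefault(uf.find((r, c)), set()).add(uid)
    unit_ids = sorted({u for s in comp_units.values() for u in s})
    uuf = UnionFind(unit_ids)
    for members in comp_units.values():
        members = sorted(members)
        for a, b in zip(members, members[1:]):
            uuf.union(a, b)
    groups: dict = {}
    for u in unit_ids:
        groups.setdefault(uuf.find(u), set()).add(u)
    return [frozenset(g) for g in groups.values()]
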