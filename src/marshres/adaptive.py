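"""Adaptive-capacity metrics: hardened shoreline, sinuosity, migration
space under stepped inundation scenarios, and wetland connectedness.

Inundation scenarios default to six depths above MHHW, one per foot from
0.3048 m to 1.8288 m.  Potential future marsh for a depth ``d`` means cells
that are migratable land cover (natural upland / agriculture — developed and
impervious classes are excluded), not currently marsh, with
``MHHW <= elevation < MHHW + d``, and hydrologically connected to existing
marsh or open water through cells that are themselves flooded, water or
marsh.  Connectivity is 4-connected and can be disabled for an
"unconnected" (bathtub) variant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage

from .landscape import (
    ClassTable,
    ElevationGrid,
    LandCoverGrid,
    MarshUnit,
    ShorelineSegment,
    TidalSurface,
)

__all__ = [
    "ScenarioSet",
    "ConnectednessResult",
    "pct_hardened_shoreline",
    "shoreline_complexity",
    "migration_candidates",
    "migration_ratio",
    "connectedness",
]

FOOT = 0.3048

_STRUCTURE_4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass(frozen=True)
class ScenarioSet:
    """Ordered inundation increments above MHHW, in meters."""

    depths: tuple[float, ...] = tuple(i * FOOT for i in range(1, 7))

    def __post_init__(self) -> None:
        d = np.asarray(self.depths, dtype=float)
        if d.size == 0 or (d <= 0).any() or (np.diff(d) <= 0).any():
            raise ValueError("scenario depths must be strictly increasing and > 0")


# ---------------------------------------------------------------------------
# shoreline metrics
# ---------------------------------------------------------------------------

def pct_hardened_shoreline(segments: list[ShorelineSegment]) -> float:
    """Hardened length as a percent of total shoreline length."""
    total = sum(s.length for s in segments)
    if total <= 0:
        return float("nan")
    hard = sum(s.length for s in segments if s.hardened)
    return 100.0 * hard / total


def _split_ring(vertices: np.ndarray) -> list[np.ndarray]:
    """Split a closed ring into two open polylines at its two most distant
    vertices (deterministic; preserves total length)."""
    ring = vertices[:-1]  # drop duplicated closing vertex
    n = len(ring)
    d2 = np.sum((ring[:, None, :] - ring[None, :, :]) ** 2, axis=-1)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    i, j = min(i, j), max(i, j)
    part_a = ring[i : j + 1]
    part_b = np.vstack([ring[j:], ring[: i + 1]])
    return [part_a, part_b]


def _segment_sinuosity(vertices: np.ndarray) -> tuple[float, float] | None:
    length = float(np.sum(np.hypot(*np.diff(vertices, axis=0).T)))
    chord = float(np.hypot(*(vertices[-1] - vertices[0])))
    if chord <= 0:
        warnings.warn("skipping degenerate shoreline segment (coincident endpoints)")
        return None
    return length / chord, length


def shoreline_complexity(segments: list[ShorelineSegment]) -> float:
    """Length-weighted mean sinuosity (path length / endpoint distance).

    Closed rings are split at their two most distant vertices into two open
    polylines before measuring.  Always >= 1 for valid input; open segments
    with coincident endpoints are skipped with a warning.
    """
    parts: list[np.ndarray] = []
    for seg in segments:
        if seg.is_closed and len(seg.vertices) > 3:
            parts.extend(_split_ring(seg.vertices))
        else:
            parts.append(seg.vertices)
    num = 0.0
    den = 0.0
    for verts in parts:
        res = _segment_sinuosity(verts)
        if res is None:
            continue
        sinuosity, length = res
        num += sinuosity * length
        den += length
    if den == 0:
        return float("nan")
    return num / den


# ---------------------------------------------------------------------------
# migration space
# ---------------------------------------------------------------------------

def _grid_context(
    landcover: LandCoverGrid,
    class_table: ClassTable,
    elevation: ElevationGrid,
    tides: TidalSurface,
):
    codes = landcover.codes
    valid = codes != landcover.nodata
    marsh = class_table.flag_grid(codes, "is_marsh", landcover.nodata) & valid
    water = class_table.flag_grid(codes, "is_water", landcover.nodata) & valid
    migratable = class_table.flag_grid(codes, "is_migratable", landcover.nodata) & valid
    elev = elevation.elevation
    mhhw = tides.mhhw_grid(codes.shape)
    return marsh, water, migratable, elev, mhhw


def migration_candidates(
    landcover: LandCoverGrid,
    class_table: ClassTable,
    elevation: ElevationGrid,
    tides: TidalSurface,
    depth: float,
    connected: bool = True,
) -> np.ndarray:
    """Grid-wide potential-future-marsh mask for one inundation depth."""
    marsh, water, migratable, elev, mhhw = _grid_context(
        landcover, class_table, elevation, tides
    )
    with np.errstate(invalid="ignore"):
        in_band = (elev >= mhhw) & (elev < mhhw + depth)
    candidates = migratable & ~marsh & in_band
    if not connected:
        return candidates
    with np.errstate(invalid="ignore"):
        flooded = elev < mhhw + depth
    passable = flooded | water | marsh
    comp, _ = ndimage.label(passable, structure=_STRUCTURE_4)
    seeded = np.unique(comp[(marsh | water) & (comp > 0)])
    reachable = np.isin(comp, seeded) & (comp > 0)
    return candidates & reachable


def migration_ratio(
    landcover: LandCoverGrid,
    class_table: ClassTable,
    elevation: ElevationGrid,
    tides: TidalSurface,
    unit_mask: np.ndarray,
    scenarios: ScenarioSet | None = None,
    connected: bool = True,
) -> float:
    """Mean over scenarios of (potential future marsh area in the unit) /
    (current marsh area of the unit).

    Connectivity is evaluated on the full grid; the migration space credited
    to the unit is restricted to cells inside its own polygon.
    """
    scenarios = scenarios or ScenarioSet()
    marsh, _, _, _, _ = _grid_context(landcover, class_table, elevation, tides)
    current = int((marsh & unit_mask).sum())
    if current == 0:
        return float("nan")
    ratios = []
    for depth in scenarios.depths:
        cand = migration_candidates(
            landcover, class_table, elevation, tides, depth, connected=connected
        )
        ratios.append(int((cand & unit_mask).sum()) / current)
    return float(np.mean(ratios))


# ---------------------------------------------------------------------------
# connectedness
# ---------------------------------------------------------------------------

@dataclass
class ConnectednessResult:
    """Per-unit connectedness scores plus the group structure behind them.

    ``score`` is oriented so that larger is better (units whose group keeps
    all of its members under the future scenario score 0, groups that lose
    members score negative); ``raw_score`` keeps the unflipped
    ``(n_current - n_future) / n_current`` value.
    """

    score: dict[str, float] = field(default_factory=dict)
    raw_score: dict[str, float] = field(default_factory=dict)
    current_groups: dict[str, int] = field(default_factory=dict)
    future_units: set[str] = field(default_factory=set)


def _units_by_component(
    mask: np.ndarray, unit_masks: dict[str, np.ndarray]
) -> list[set[str]]:
    comp, n = ndimage.label(mask, structure=_STRUCTURE_4)
    members: dict[int, set[str]] = {}
    for uid, umask in unit_masks.items():
        for c in np.unique(comp[umask & mask]):
            if c > 0:
                members.setdefault(int(c), set()).add(uid)
    return [s for s in members.values() if s]


def connectedness(
    landcover: LandCoverGrid,
    class_table: ClassTable,
    elevation: ElevationGrid,
    tides: TidalSurface,
    units: list[MarshUnit],
    unit_masks: dict[str, np.ndarray],
    slr: float = 1.2,
    connected: bool = True,
) -> ConnectednessResult:
    """Group marsh units connected by contiguous marsh footprint, now and
    under a sea-level-rise scenario, and score the attrition per group.

    Future marsh = current marsh cells that stay at or above the raised mean
    tide level (MTL + ``slr``) plus the migration space at depth ``slr``.
    Within each current group the raw score is
    ``(n_current_units - n_future_units) / n_current_units``; every member
    receives the group value, stored sign-flipped so larger = better.
    """
    marsh, water, _, elev, _ = _grid_context(landcover, class_table, elevation, tides)
    mtl = tides.mtl_grid(marsh.shape)
    with np.errstate(invalid="ignore"):
        surviving = marsh & ~(elev < mtl + slr)
    future = surviving | migration_candidates(
        landcover, class_table, elevation, tides, slr, connected=connected
    )

    has_marsh = {uid for uid, m in unit_masks.items() if (marsh & m).any()}
    # units sharing a marsh component merge transitively into one group
    graph = nx.Graph()
    graph.add_nodes_from(has_marsh)
    for comp_units in _units_by_component(marsh, unit_masks):
        graph.add_edges_from(zip(list(comp_units)[:-1], list(comp_units)[1:]))
    future_units = {uid for uid in has_marsh if (future & unit_masks[uid]).any()}

    result = ConnectednessResult(future_units=future_units)
    for gi, group in enumerate(nx.connected_components(graph)):
        n_cur = len(group)
        n_fut = len(group & future_units)
        raw = (n_cur - n_fut) / n_cur
        for uid in group:
            result.raw_score[uid] = raw
            result.score[uid] = -raw
            result.current_groups[uid] = gi
    for unit in units:
        if unit.unit_id not in has_marsh:
            result.score[unit.unit_id] = float("nan")
            result.raw_score[unit.unit_id] = float("nan")
    return result
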