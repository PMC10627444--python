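"""Current-condition metrics: core/edge structure and surrounding land cover.

A marsh cell is *edge* when at least one neighbour (4- or 8-connected,
default 4) is a non-nodata, non-marsh cell; edge cells whose offending
neighbour is additionally unvegetated (open water, flat, bare, developed)
are *unvegetated edge*.  Counts are in cells; with a uniform cell size the
downstream decile ranking is invariant to the metric's constant factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .landscape import ClassTable, LandCoverGrid, MarshUnit

__all__ = [
    "CoreEdgeLabels",
    "classify_core_edge",
    "area_to_edge_ratio",
    "unvegetated_edge_ratio",
    "landcover_fractions",
]

NON_MARSH, CORE, VEGETATED_EDGE, UNVEGETATED_EDGE = 0, 1, 2, 3

_OFFSETS_4 = ((-1, 0), (1, 0), (0, -1), (0, 1))
_OFFSETS_8 = _OFFSETS_4 + ((-1, -1), (-1, 1), (1, -1), (1, 1))


@dataclass
class CoreEdgeLabels:
    """Per-cell core/edge labels for the marsh cells of one unit."""

    labels: np.ndarray  # int8 grid of NON_MARSH/CORE/VEGETATED_EDGE/UNVEGETATED_EDGE

    @property
    def n_core(self) -> int:
        return int(np.count_nonzero(self.labels == CORE))

    @property
    def n_edge(self) -> int:
        return int(np.count_nonzero(self.labels >= VEGETATED_EDGE))

    @property
    def n_unvegetated_edge(self) -> int:
        return int(np.count_nonzero(self.labels == UNVEGETATED_EDGE))

    @property
    def n_marsh(self) -> int:
        return self.n_core + self.n_edge

    @property
    def is_empty(self) -> bool:
        return self.n_marsh == 0


def _shift(mask: np.ndarray, dr: int, dc: int) -> np.ndarray:
    """Neighbour mask shifted by (dr, dc); out-of-grid neighbours are False."""
    out = np.zeros_like(mask)
    rows, cols = mask.shape
    out[max(dr, 0) : rows + min(dr, 0), max(dc, 0) : cols + min(dc, 0)] = mask[
        max(-dr, 0) : rows + min(-dr, 0), max(-dc, 0) : cols + min(-dc, 0)
    ]
    return out


def classify_core_edge(
    landcover: LandCoverGrid,
    class_table: ClassTable,
    unit_mask: np.ndarray,
    connectivity: int = 4,
) -> CoreEdgeLabels:
    """Label each marsh cell of a unit as core, vegetated edge or
    unvegetated edge.

    Neighbours are taken from the full grid (marsh in an adjacent unit still
    counts as marsh); off-grid neighbours are ignored.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    if not unit_mask.any():
        raise ValueError("unit_mask is empty")
    codes = landcover.codes
    valid = codes != landcover.nodata
    marsh = class_table.flag_grid(codes, "is_marsh", landcover.nodata) & valid
    vegetated = class_table.flag_grid(codes, "is_vegetated", landcover.nodata) & valid
    non_marsh_nb = valid & ~marsh
    unveg_nb = non_marsh_nb & ~vegetated

    offsets = _OFFSETS_4 if connectivity == 4 else _OFFSETS_8
    any_non_marsh = np.zeros_like(marsh)
    any_unveg = np.zeros_like(marsh)
    for dr, dc in offsets:
        any_non_marsh |= _shift(non_marsh_nb, dr, dc)
        any_unveg |= _shift(unveg_nb, dr, dc)

    unit_marsh = marsh & unit_mask
    labels = np.zeros(codes.shape, dtype=np.int8)
    labels[unit_marsh] = CORE
    labels[unit_marsh & any_non_marsh] = VEGETATED_EDGE
    labels[unit_marsh & any_unveg] = UNVEGETATED_EDGE
    return CoreEdgeLabels(labels)


def area_to_edge_ratio(labels: CoreEdgeLabels) -> float:
    """Core cell count over edge cell count; an all-core unit (no exposed
    edge) returns n_core / 1 by convention."""
    if labels.is_empty:
        return float("nan")
    return labels.n_core / max(labels.n_edge, 1)


def unvegetated_edge_ratio(labels: CoreEdgeLabels) -> float:
    """Fraction of edge cells that touch unvegetated non-marsh; 0 when the
    unit has no edge at all."""
    if labels.is_empty:
        return float("nan")
    if labels.n_edge == 0:
        return 0.0
    return labels.n_unvegetated_edge / labels.n_edge


def landcover_fractions(
    landcover: LandCoverGrid,
    class_table: ClassTable,
    unit: MarshUnit,
    buffer_m: float = 150.0,
) -> dict[str, float]:
    """Percent impervious / natural / agricultural cover within the unit
    polygon dilated by ``buffer_m``.

    Membership is by cell-center test; nodata cells are excluded from the
    denominator.  Impervious percent is intensity-weighted by each class's
    impervious fraction.
    """
    import shapely

    buffered = unit.boundary.buffer(buffer_m)
    xs, ys = landcover.cell_centers()
    inside = shapely.contains_xy(buffered, xs.ravel(), ys.ravel()).reshape(xs.shape)
    inside &= landcover.codes != landcover.nodata
    n = int(inside.sum())
    if n == 0:
        return {
            "pct_impervious": float("nan"),
            "pct_natural": float("nan"),
            "pct_agricultural": float("nan"),
        }
    codes = landcover.codes
    imperv = class_table.impervious_grid(codes, landcover.nodata)
    natural = class_table.flag_grid(codes, "is_natural", landcover.nodata)
    agri = class_table.flag_grid(codes, "is_agricultural", landcover.nodata)
    return {
        "pct_impervious": 100.0 * float(imperv[inside].sum()) / n,
        "pct_natural": 100.0 * float(natural[inside].sum()) / n,
        "pct_agricultural": 100.0 * float(agri[inside].sum()) / n,
    }
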