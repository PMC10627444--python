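"""Vulnerability metrics: soil erodibility, tidal range, marsh below datum.

"Below" is a strict inequality throughout — a cell sitting exactly at the
datum counts as not below.
"""

from __future__ import annotations

import numpy as np

from .landscape import ClassTable, ElevationGrid, ErodibilityGrid, LandCoverGrid, TidalSurface

__all__ = ["mean_erodibility", "tidal_range", "pct_marsh_below", "marsh_mask"]


def marsh_mask(
    landcover: LandCoverGrid, class_table: ClassTable, unit_mask: np.ndarray
) -> np.ndarray:
    """Marsh cells of one unit."""
    valid = landcover.codes != landcover.nodata
    return class_table.flag_grid(landcover.codes, "is_marsh", landcover.nodata) & valid & unit_mask


def mean_erodibility(erodibility: ErodibilityGrid, unit_mask: np.ndarray) -> float:
    """Arithmetic mean K factor over the unit's non-nodata cells."""
    k = erodibility.k_factor[unit_mask]
    k = k[np.isfinite(k)]
    if k.size == 0:
        return float("nan")
    return float(k.mean())


def tidal_range(tides: TidalSurface, unit_mask: np.ndarray) -> float:
    """Mean MHHW - MLLW over the unit, meters."""
    shape = unit_mask.shape
    rng = tides.mhhw_grid(shape) - tides.mllw_grid(shape)
    vals = rng[unit_mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return float("nan")
    return float(vals.mean())


def pct_marsh_below(
    level: str,
    elevation: ElevationGrid,
    tides: TidalSurface,
    marsh: np.ndarray,
) -> float:
    """Percent of marsh cells strictly below MHHW or MTL.

    ``level`` is ``"mhhw"`` or ``"mtl"``; the datum is evaluated per cell
    when the tidal surface is gridded.
    """
    if level not in ("mhhw", "mtl"):
        raise ValueError("level must be 'mhhw' or 'mtl'")
    if not marsh.any():
        return float("nan")
    datum = tides.mhhw_grid(marsh.shape) if level == "mhhw" else tides.mtl_grid(marsh.shape)
    elev = elevation.elevation[marsh]
    dat = datum[marsh]
    ok = np.isfinite(elev) & np.isfinite(dat)
    if not ok.any():
        return float("nan")
    return 100.0 * float(np.count_nonzero(elev[ok] < dat[ok])) / int(marsh.sum())
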