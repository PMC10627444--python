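"""Readers and writers for the interchange formats.

Everything is plain text: rasters as ESRI ASCII grids (``.asc``), vectors as
GeoJSON, tables as CSV (UTF-8, ``.`` decimal, ``unit_id`` key), class table
and configuration as YAML.  A landscape directory bundles the lot under a
``manifest.yaml``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import mapping, shape

from .landscape import (
    ClassTable,
    ElevationGrid,
    ErodibilityGrid,
    Landscape,
    LandCoverGrid,
    MarshUnit,
    ShorelineSegment,
    TidalSurface,
)

__all__ = [
    "write_ascii_grid",
    "read_ascii_grid",
    "write_landscape",
    "read_landscape",
    "read_metric_table",
    "write_metric_table",
]

_FLOAT_NODATA = -99999.0


def write_ascii_grid(
    path,
    data: np.ndarray,
    cell_size: float,
    origin: tuple[float, float],
    nodata,
    integer: bool = False,
) -> None:
    """ESRI ASCII grid; ``origin`` is the north-west corner."""
    rows, cols = data.shape
    x0, y0 = origin
    out = np.asarray(data)
    if not integer:
        out = np.where(np.isfinite(out.astype(float)), out, _FLOAT_NODATA)
        nodata = _FLOAT_NODATA
    header = (
        f"ncols {cols}\nnrows {rows}\n"
        f"xllcorner {x0:.10g}\nyllcorner {y0 - rows * cell_size:.10g}\n"
        f"cellsize {cell_size:.10g}\nNODATA_value {nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%d" if integer else "%.10g")


def read_ascii_grid(path, integer: bool = False):
    """Returns (data, cell_size, origin_nw, nodata)."""
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, value = fh.readline().split()
            header[key.lower()] = float(value)
        data = np.loadtxt(fh, ndmin=2)
    rows = int(header["nrows"])
    cell = header["cellsize"]
    origin = (header["xllcorner"], header["yllcorner"] + rows * cell)
    nodata = header.get("nodata_value")
    if integer:
        data = data.astype(np.int64)
        nodata = int(nodata)
    else:
        data = data.astype(float)
        data[data == nodata] = np.nan
    return data, cell, origin, nodata


def _segments_to_geojson(segments: list[ShorelineSegment]) -> dict:
    return {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": {
                    "type": "LineString",
                    "coordinates": [[float(x), float(y)] for x, y in seg.vertices],
                },
                "properties": {"hardened": bool(seg.hardened), "unit_id": seg.unit_id},
            }
            for seg in segments
        ],
    }


def _units_to_geojson(units: list[MarshUnit]) -> dict:
    return {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": mapping(u.boundary),
                "properties": {"unit_id": u.unit_id, **u.groups},
            }
            for u in units
        ],
    }


def write_landscape(landscape: Landscape, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    lc = landscape.landcover
    write_ascii_grid(d / "landcover.asc", lc.codes, lc.cell_size, lc.origin, lc.nodata, integer=True)
    write_ascii_grid(d / "elevation.asc", landscape.elevation.elevation, lc.cell_size, lc.origin, None)
    write_ascii_grid(d / "erodibility.asc", landscape.erodibility.k_factor, lc.cell_size, lc.origin, None)

    tides = landscape.tides
    manifest: dict = {
        "crs_id": lc.crs_id,
        "vertical_datum": landscape.elevation.datum,
        "nodata": int(lc.nodata),
    }
    scalar = all(np.asarray(getattr(tides, f)).ndim == 0 for f in ("mhhw", "mtl", "mllw"))
    if scalar:
        manifest["tides"] = {f: float(getattr(tides, f)) for f in ("mhhw", "mtl", "mllw")}
    else:
        manifest["tides"] = "grids"
        for f in ("mhhw", "mtl", "mllw"):
            write_ascii_grid(d / f"tide_{f}.asc", tides._as_grid(getattr(tides, f), lc.shape), lc.cell_size, lc.origin, None)

    with open(d / "class_table.yaml", "w") as fh:
        yaml.safe_dump(landscape.class_table.to_dict(), fh, sort_keys=True)
    with open(d / "shorelines.geojson", "w") as fh:
        json.dump(_segments_to_geojson(landscape.shorelines), fh)
    with open(d / "units.geojson", "w") as fh:
        json.dump(_units_to_geojson(landscape.units), fh)
    with open(d / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)


def read_landscape(directory) -> Landscape:
    """Read a landscape directory; alignment problems and unknown land-cover
    codes are hard errors (grids are validated, never resampled)."""
    d = Path(directory)
    with open(d / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    crs = manifest["crs_id"]
    codes, cell, origin, nodata = read_ascii_grid(d / "landcover.asc", integer=True)
    elev, cell_e, origin_e, _ = read_ascii_grid(d / "elevation.asc")
    erod, cell_k, origin_k, _ = read_ascii_grid(d / "erodibility.asc")

    landcover = LandCoverGrid(codes, cell, origin, crs, nodata=nodata)
    elevation = ElevationGrid(elev, cell_e, origin_e, crs, datum=manifest["vertical_datum"])
    erodibility = ErodibilityGrid(erod, cell_k, origin_k, crs)

    if manifest["tides"] == "grids":
        tide_vals = {}
        for f in ("mhhw", "mtl", "mllw"):
            tide_vals[f], _, _, _ = read_ascii_grid(d / f"tide_{f}.asc")
        tides = TidalSurface(**tide_vals)
    else:
        tides = TidalSurface(**{k: float(v) for k, v in manifest["tides"].items()})

    with open(d / "class_table.yaml") as fh:
        class_table = ClassTable.from_dict(yaml.safe_load(fh))
    with open(d / "shorelines.geojson") as fh:
        seg_fc = json.load(fh)
    shorelines = [
        ShorelineSegment(
            vertices=np.asarray(f["geometry"]["coordinates"], dtype=float),
            hardened=bool(f["properties"]["hardened"]),
            unit_id=f["properties"]["unit_id"],
        )
        for f in seg_fc["features"]
    ]
    with open(d / "units.geojson") as fh:
        unit_fc = json.load(fh)
    units = []
    for f in unit_fc["features"]:
        props = dict(f["properties"])
        uid = props.pop("unit_id")
        units.append(MarshUnit(unit_id=uid, boundary=shape(f["geometry"]), groups=props))

    return Landscape(landcover, elevation, tides, erodibility, shorelines, units, class_table)


def read_metric_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "unit_id" not in df.columns:
        raise ValueError("metric CSV must carry a unit_id column")
    if df["unit_id"].duplicated().any():
        raise ValueError("unit_id values must be unique")
    return df.set_index("unit_id")


def write_metric_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=True, index_label="unit_id")
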