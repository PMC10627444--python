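"""Domain types for geospatial inputs plus seeded synthetic generators.

All geometry is planar, in meters, in a projected CRS that is recorded but
never reprojected.  Raster convention: row 0 is the north edge; the center of
cell (row, col) sits at ``origin + ((col + 0.5) * cell_size,
-(row + 0.5) * cell_size)``.  Areas are cell counts times ``cell_size**2``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage
from shapely.geometry import Polygon, box

__all__ = [
    "ClassInfo",
    "ClassTable",
    "LandCoverGrid",
    "ElevationGrid",
    "TidalSurface",
    "ErodibilityGrid",
    "ShorelineSegment",
    "MarshUnit",
    "Landscape",
    "GeneratorParams",
    "MetricSpec",
    "DEFAULT_CLASS_TABLE",
    "DEFAULT_METRIC_SPECS",
    "generate_landscape",
    "generate_metric_table",
    "fill_nodata_nearest",
]


# ---------------------------------------------------------------------------
# class-attribute table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassInfo:
    """Semantic flags attached to one land-cover class code."""

    label: str
    is_marsh: bool = False
    is_vegetated: bool = False
    is_water: bool = False
    impervious_fraction: float = 0.0
    is_natural: bool = False
    is_agricultural: bool = False
    is_migratable: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.impervious_fraction <= 1.0:
            raise ValueError(
                f"impervious_fraction must be in [0, 1], got {self.impervious_fraction}"
            )
        if self.is_marsh and self.is_water:
            raise ValueError(f"class {self.label!r}: is_marsh implies not is_water")
        if self.impervious_fraction > 0 and (self.is_natural or self.is_marsh):
            raise ValueError(
                f"class {self.label!r}: impervious cover excludes natural/marsh flags"
            )


class ClassTable:
    """Mapping from integer class code to :class:`ClassInfo`.

    Provides vectorized flag lookups over a 2-D code grid; codes absent from
    the table raise, so unknown land-cover codes are always a hard error.
    """

    def __init__(self, entries: Mapping[int, ClassInfo]):
        if not entries:
            raise ValueError("ClassTable needs at least one entry")
        self.entries: dict[int, ClassInfo] = dict(entries)

    def __contains__(self, code: int) -> bool:
        return code in self.entries

    def __getitem__(self, code: int) -> ClassInfo:
        return self.entries[code]

    def codes(self) -> list[int]:
        return sorted(self.entries)

    def _lookup(self, codes: np.ndarray, attr: str, fill, nodata: int) -> np.ndarray:
        unknown = set(np.unique(codes)) - set(self.entries) - {nodata}
        if unknown:
            raise KeyError(f"land-cover codes not in ClassTable: {sorted(unknown)}")
        out = np.full(codes.shape, fill, dtype=np.asarray(fill).dtype)
        for code, info in self.entries.items():
            out[codes == code] = getattr(info, attr)
        return out

    def flag_grid(self, codes: np.ndarray, attr: str, nodata: int) -> np.ndarray:
        """Boolean grid of the given flag; nodata cells are False."""
        return self._lookup(codes, attr, False, nodata)

    def impervious_grid(self, codes: np.ndarray, nodata: int) -> np.ndarray:
        return self._lookup(codes, "impervious_fraction", 0.0, nodata)

    def to_dict(self) -> dict:
        return {
            int(code): dataclasses.asdict(info) for code, info in self.entries.items()
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ClassTable":
        return cls({int(code): ClassInfo(**attrs) for code, attrs in d.items()})


#: Default synthetic class codes.  Semantics mirror 30 m coastal land-cover
#: products (open water, estuarine emergent marsh, unvegetated flat, natural
#: upland, agriculture, three developed intensities); fully user-overridable.
DEFAULT_CLASS_TABLE = ClassTable(
    {
        1: ClassInfo("open_water", is_water=True),
        2: ClassInfo("estuarine_emergent_marsh", is_marsh=True, is_vegetated=True),
        3: ClassInfo("unvegetated_flat"),
        4: ClassInfo(
            "natural_upland", is_vegetated=True, is_natural=True, is_migratable=True
        ),
        5: ClassInfo(
            "agriculture", is_vegetated=True, is_agricultural=True, is_migratable=True
        ),
        6: ClassInfo("developed_low", impervious_fraction=0.25),
        7: ClassInfo("developed_medium", impervious_fraction=0.60),
        8: ClassInfo("developed_high", impervious_fraction=0.90),
    }
)


# ---------------------------------------------------------------------------
# grids
# ---------------------------------------------------------------------------

@dataclass
class _BaseGrid:
    data: np.ndarray
    cell_size: float
    origin: tuple[float, float]  # (x, y) of the north-west corner
    crs_id: str = "EPSG:32619"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2 or self.data.size == 0:
            raise ValueError("grid must be a non-empty 2-D array")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinate grids of every cell center."""
        rows, cols = self.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(cols) + 0.5) * self.cell_size
        ys = y0 - (np.arange(rows) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def aligned_with(self, other: "_BaseGrid") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.cell_size, other.cell_size)
            and np.allclose(self.origin, other.origin)
        )


@dataclass
class LandCoverGrid(_BaseGrid):
    nodata: int = -1

    def __post_init__(self) -> None:
        super().__post_init__()
        self.data = self.data.astype(np.int64)

    @property
    def codes(self) -> np.ndarray:
        return self.data

    def validate_codes(self, class_table: ClassTable) -> None:
        present = set(np.unique(self.data)) - {self.nodata}
        unknown = present - set(class_table.entries)
        if unknown:
            raise ValueError(f"unknown land-cover codes: {sorted(unknown)}")


@dataclass
class ElevationGrid(_BaseGrid):
    """Elevations in meters relative to a named vertical datum; NaN = nodata."""

    datum: str = "NAVD88"

    def __post_init__(self) -> None:
        super().__post_init__()
        self.data = self.data.astype(np.float64)

    @property
    def elevation(self) -> np.ndarray:
        return self.data


@dataclass
class ErodibilityGrid(_BaseGrid):
    """Unitless soil-erodibility K factor; NaN = nodata."""

    def __post_init__(self) -> None:
        super().__post_init__()
        self.data = self.data.astype(np.float64)
        finite = self.data[np.isfinite(self.data)]
        if finite.size and (finite < 0).any():
            raise ValueError("K factor must be >= 0 where defined")

    @property
    def k_factor(self) -> np.ndarray:
        return self.data


@dataclass
class TidalSurface:
    """MHHW / MTL / MLLW, each either a scalar or a grid aligned with the DEM.

    All values share the elevation grid's vertical datum and must satisfy
    ``mllw <= mtl <= mhhw`` wherever defined (NaN marks undefined cells).
    """

    mhhw: float | np.ndarray
    mtl: float | np.ndarray
    mllw: float | np.ndarray

    def __post_init__(self) -> None:
        m_hi = np.asarray(self.mhhw, dtype=float)
        m_md = np.asarray(self.mtl, dtype=float)
        m_lo = np.asarray(self.mllw, dtype=float)
        with np.errstate(invalid="ignore"):
            bad = (m_lo > m_md) | (m_md > m_hi)
        if np.any(bad):
            raise ValueError("tidal datums must satisfy mllw <= mtl <= mhhw")

    def _as_grid(self, value: float | np.ndarray, shape: tuple[int, int]) -> np.ndarray:
        arr = np.asarray(value, dtype=float)
        if arr.ndim == 0:
            return np.full(shape, float(arr))
        if arr.shape != shape:
            raise ValueError(f"tidal grid shape {arr.shape} != raster shape {shape}")
        return arr

    def mhhw_grid(self, shape: tuple[int, int]) -> np.ndarray:
        return self._as_grid(self.mhhw, shape)

    def mtl_grid(self, shape: tuple[int, int]) -> np.ndarray:
        return self._as_grid(self.mtl, shape)

    def mllw_grid(self, shape: tuple[int, int]) -> np.ndarray:
        return self._as_grid(self.mllw, shape)


def fill_nodata_nearest(grid: np.ndarray) -> np.ndarray:
    """Fill NaN cells with the value of the nearest defined cell.

    Convenience for gappy interpolated tidal surfaces; no claim of fidelity to
    any particular interpolation scheme.
    """
    arr = np.asarray(grid, dtype=float)
    mask = np.isnan(arr)
    if not mask.any():
        return arr.copy()
    if mask.all():
        raise ValueError("cannot fill a grid with no defined cells")
    idx = ndimage.distance_transform_edt(mask, return_distances=False, return_indices=True)
    return arr[tuple(idx)]


# ---------------------------------------------------------------------------
# vectors
# ---------------------------------------------------------------------------

@dataclass
class ShorelineSegment:
    """Open polyline in planar meters, attributed hardened/natural per unit."""

    vertices: np.ndarray  # (n, 2)
    hardened: bool
    unit_id: str

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[0] < 2 or self.vertices.shape[1] != 2:
            raise ValueError("a shoreline segment needs >= 2 planar vertices")
        if self.length <= 0:
            raise ValueError("shoreline segment must have positive length")

    @property
    def length(self) -> float:
        return float(np.sum(np.hypot(*np.diff(self.vertices, axis=0).T)))

    @property
    def is_closed(self) -> bool:
        return bool(np.allclose(self.vertices[0], self.vertices[-1]))


@dataclass
class MarshUnit:
    """Polygon + unique unit identifier (MUC) + optional grouping labels."""

    unit_id: str
    boundary: Polygon
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not isinstance(self.boundary, Polygon) or self.boundary.is_empty:
            raise ValueError(f"unit {self.unit_id!r}: boundary must be a non-empty polygon")
        if not self.boundary.is_valid or self.boundary.area <= 0:
            raise ValueError(f"unit {self.unit_id!r}: polygon invalid or degenerate")


@dataclass
class Landscape:
    landcover: LandCoverGrid
    elevation: ElevationGrid
    tides: TidalSurface
    erodibility: ErodibilityGrid
    shorelines: list[ShorelineSegment]
    units: list[MarshUnit]
    class_table: ClassTable

    def __post_init__(self) -> None:
        self.validate()
        self._mask_cache: dict[str, np.ndarray] = {}

    def validate(self) -> None:
        for other, name in (
            (self.elevation, "elevation"),
            (self.erodibility, "erodibility"),
        ):
            if not self.landcover.aligned_with(other):
                raise ValueError(f"{name} grid is not aligned with the land-cover grid")
        self.landcover.validate_codes(self.class_table)
        ids = [u.unit_id for u in self.units]
        if len(ids) != len(set(ids)):
            raise ValueError("unit_ids must be unique")
        known = set(ids)
        for seg in self.shorelines:
            if seg.unit_id not in known:
                raise ValueError(f"shoreline references unknown unit {seg.unit_id!r}")

    def unit_mask(self, unit: MarshUnit) -> np.ndarray:
        """Boolean grid of cells whose centers fall inside the unit polygon."""
        cached = self._mask_cache.get(unit.unit_id)
        if cached is not None:
            return cached
        xs, ys = self.landcover.cell_centers()
        mask = shapely.contains_xy(unit.boundary, xs.ravel(), ys.ravel()).reshape(xs.shape)
        self._mask_cache[unit.unit_id] = mask
        return mask

    def unit_shorelines(self, unit_id: str) -> list[ShorelineSegment]:
        return [s for s in self.shorelines if s.unit_id == unit_id]


# ---------------------------------------------------------------------------
# synthetic landscape generator
# ---------------------------------------------------------------------------

@dataclass
class GeneratorParams:
    """Tunables for :func:`generate_landscape`."""

    cell_size: float = 30.0
    crs_id: str = "EPSG:32619"
    mllw: float = -0.8
    mtl: float = 0.2
    mhhw: float = 1.2
    tide_jitter: float = 0.08  # per-unit datum offset amplitude, m
    noise_amplitude: float = 0.6  # elevation noise, m
    noise_scale: float = 6.0  # gaussian smoothing radius, cells
    hardened_fraction: float = 0.3
    segments_per_unit: int = 3
    upland_natural: float = 0.6
    upland_agricultural: float = 0.2  # remainder is developed (3 intensities)
    region_labels: tuple[str, ...] = ("west", "east")


def _smooth_noise(rng: np.random.Generator, shape: tuple[int, int], scale: float) -> np.ndarray:
    field_ = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=scale)
    sd = field_.std()
    return field_ / sd if sd > 0 else field_


def generate_landscape(
    seed: int,
    n_units: int,
    grid_shape: tuple[int, int],
    marsh_fraction: float,
    params: GeneratorParams | None = None,
) -> Landscape:
    """Build a deterministic synthetic landscape.

    Marsh patches sit on an elevation ramp spanning below MLLW to above
    MHHW + 2 m, bordered by open water on the low side and upland (natural /
    agricultural / developed) on the high side.  Units tile the grid as
    north-south strips; each carries a region label and a set of shoreline
    segments with a controllable hardened fraction.
    """
    params = params or GeneratorParams()
    rows, cols = grid_shape
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    if not 0.0 <= marsh_fraction <= 1.0:
        raise ValueError("marsh_fraction must be in [0, 1]")
    if cols // n_units < 2 or rows < 2:
        raise ValueError("grid too small: each unit needs at least a 2-cell-wide strip")

    rng = np.random.default_rng(seed)
    cell = params.cell_size
    origin = (0.0, rows * cell)

    # per-unit tidal constants: a shared vertical offset keeps ordering intact
    offsets = rng.uniform(-params.tide_jitter, params.tide_jitter, n_units)
    strip_edges = np.linspace(0, cols, n_units + 1).round().astype(int)
    unit_of_col = np.zeros(cols, dtype=int)
    for i in range(n_units):
        unit_of_col[strip_edges[i] : strip_edges[i + 1]] = i
    mhhw = np.empty(grid_shape)
    mtl = np.empty(grid_shape)
    mllw = np.empty(grid_shape)
    for i in range(n_units):
        sel = unit_of_col == i
        mhhw[:, sel] = params.mhhw + offsets[i]
        mtl[:, sel] = params.mtl + offsets[i]
        mllw[:, sel] = params.mllw + offsets[i]

    # elevation: north (row 0) upland down to open water in the south
    lo = params.mllw - 1.0
    hi = params.mhhw + 2.5
    ramp = hi - (hi - lo) * (np.arange(rows) + 0.5)[:, None] / rows
    elev = ramp + params.noise_amplitude * _smooth_noise(rng, grid_shape, params.noise_scale)

    # marsh: the top-k most suitable cells, k fixed by the requested fraction
    n_cells = rows * cols
    k = int(round(marsh_fraction * n_cells))
    band_center = (mtl + mhhw) / 2.0
    suitability = -np.abs(elev - band_center) + 0.4 * _smooth_noise(
        rng, grid_shape, params.noise_scale
    )
    marsh = np.zeros(grid_shape, dtype=bool)
    if k > 0:
        threshold = np.partition(suitability.ravel(), n_cells - k)[n_cells - k]
        marsh = suitability >= threshold
        # ties at the threshold could overshoot; trim deterministically
        excess = int(marsh.sum()) - k
        if excess > 0:
            tied = np.flatnonzero((suitability == threshold).ravel() & marsh.ravel())
            marsh.ravel()[tied[:excess]] = False

    codes = np.full(grid_shape, 4, dtype=np.int64)  # natural upland baseline
    upland = ~marsh & (elev >= mtl)
    low = ~marsh & (elev < mtl)
    codes[low & (elev < mllw)] = 1  # open water
    codes[low & (elev >= mllw)] = 3  # unvegetated flat
    # carve agriculture / developed out of the upland with smooth fields
    ag_field = _smooth_noise(rng, grid_shape, params.noise_scale)
    dev_field = _smooth_noise(rng, grid_shape, params.noise_scale)
    p_dev = max(0.0, 1.0 - params.upland_natural - params.upland_agricultural)
    ag_cut = np.quantile(ag_field, 1.0 - params.upland_agricultural) if params.upland_agricultural > 0 else np.inf
    dev_cut = np.quantile(dev_field, 1.0 - p_dev) if p_dev > 0 else np.inf
    is_ag = upland & (ag_field >= ag_cut)
    is_dev = upland & ~is_ag & (dev_field >= dev_cut)
    codes[is_ag] = 5
    intensity = rng.integers(6, 9, size=grid_shape)
    codes[is_dev] = intensity[is_dev]
    codes[marsh] = 2

    landcover = LandCoverGrid(codes, cell, origin, params.crs_id, nodata=-1)
    elevation = ElevationGrid(elev, cell, origin, params.crs_id)
    tides = TidalSurface(mhhw=mhhw, mtl=mtl, mllw=mllw)
    k_factor = np.clip(
        0.28 + 0.1 * _smooth_noise(rng, grid_shape, params.noise_scale), 0.02, None
    )
    erod = ErodibilityGrid(k_factor, cell, origin, params.crs_id)

    units: list[MarshUnit] = []
    regions = params.region_labels
    for i in range(n_units):
        x0 = strip_edges[i] * cell
        x1 = strip_edges[i + 1] * cell
        poly = box(x0, 0.0, x1, rows * cell)
        units.append(
            MarshUnit(
                unit_id=f"MU{i:04d}",
                boundary=poly,
                groups={"region": regions[i * len(regions) // n_units]},
            )
        )

    shorelines = _generate_shorelines(rng, units, params)
    return Landscape(landcover, elevation, tides, erod, shorelines, units, DEFAULT_CLASS_TABLE)


def _generate_shorelines(
    rng: np.random.Generator, units: Sequence[MarshUnit], params: GeneratorParams
) -> list[ShorelineSegment]:
    """Wiggly west-east polylines per unit; hardened length fraction is
    matched as closely as the per-unit segment count allows."""
    segments: list[ShorelineSegment] = []
    n_seg = max(1, params.segments_per_unit)
    n_hard = int(round(params.hardened_fraction * n_seg))
    for unit in units:
        x_min, y_min, x_max, y_max = unit.boundary.bounds
        hardened_flags = np.zeros(n_seg, dtype=bool)
        hardened_flags[rng.permutation(n_seg)[:n_hard]] = True
        for j in range(n_seg):
            y0 = y_min + (j + 1) * (y_max - y_min) / (n_seg + 1)
            n_pts = 12
            xs = np.linspace(x_min, x_max, n_pts)
            ys = y0 + np.cumsum(rng.normal(0, 5.0, n_pts))
            segments.append(
                ShorelineSegment(
                    vertices=np.column_stack([xs, ys]),
                    hardened=bool(hardened_flags[j]),
                    unit_id=unit.unit_id,
                )
            )
    return segments


# ---------------------------------------------------------------------------
# synthetic metric-table generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MetricSpec:
    """Normal sampling parameters for one metric, clipped to [low, high]."""

    mean: float
    sd: float
    low: float = -np.inf
    high: float = np.inf

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.low > self.high:
            raise ValueError("low must be <= high")


#: Defaults keep the sampling mean far from the clip bounds so that clipping
#: is negligible and sample means track the specified means.
DEFAULT_METRIC_SPECS: dict[str, MetricSpec] = {
    "area_to_edge_ratio": MetricSpec(1.0, 0.3, low=0.0),
    "unveg_edge_ratio": MetricSpec(0.4, 0.12, low=0.0, high=1.0),
    "pct_impervious": MetricSpec(20.0, 6.0, low=0.0, high=100.0),
    "pct_natural": MetricSpec(50.0, 12.0, low=0.0, high=100.0),
    "pct_agricultural": MetricSpec(15.0, 5.0, low=0.0, high=100.0),
    "soil_erodibility": MetricSpec(0.3, 0.08, low=0.0),
    "tidal_range_m": MetricSpec(2.0, 0.5, low=0.0),
    "pct_below_mhhw": MetricSpec(60.0, 12.0, low=0.0, high=100.0),
    "pct_below_mtl": MetricSpec(25.0, 8.0, low=0.0, high=100.0),
    "pct_hardened": MetricSpec(30.0, 9.0, low=0.0, high=100.0),
    "shoreline_complexity": MetricSpec(1.6, 0.2, low=1.0),
    "migration_ratio": MetricSpec(0.5, 0.15, low=0.0),
    "connectedness": MetricSpec(-0.2, 0.07, low=-1.0, high=0.0),
}


def generate_metric_table(
    seed: int,
    n_units: int,
    spec: Mapping[str, MetricSpec] | None = None,
    group_labels: tuple[str, ...] = ("west", "east"),
) -> pd.DataFrame:
    """Draw a per-unit raw metric table directly, bypassing rasters.

    Deterministic per seed; one row per synthetic unit, keyed ``unit_id``,
    with a round-robin ``region`` group column.
    """
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    specs = dict(DEFAULT_METRIC_SPECS)
    if spec:
        specs.update(spec)
    rng = np.random.default_rng(seed)
    data: dict[str, object] = {"unit_id": [f"MU{i:04d}" for i in range(n_units)]}
    for name, ms in specs.items():
        draws = rng.normal(ms.mean, ms.sd, n_units) if ms.sd > 0 else np.full(n_units, ms.mean)
        data[name] = np.clip(draws, ms.low, ms.high)
    if group_labels:
        data["region"] = [
            group_labels[i * len(group_labels) // n_units] for i in range(n_units)
        ]
    return pd.DataFrame(data).set_index("unit_id")
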