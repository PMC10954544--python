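"""Core data types: chemistry panels, sample tables, study grids and territories.

All coordinates are WGS84 longitude/latitude in decimal degrees.  Grids are
regular lon/lat lattices; cells are identified by a single row-major index
(latitude rows south to north as the outer loop, longitude west to east as
the inner loop).  That ordering is relied on downstream for deterministic
tie-breaking, so it must never change.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import shape as shapely_shape

ISOTOPE_RATIO = "isotope_ratio"
TRACE_ELEMENT = "trace_element"

#: Stable isotope ratios measured on every sample (delta notation, per mil).
ISOTOPE_NAMES = ("d13C", "d2H", "d2H_nit", "d15N", "d18O", "d34S")

#: XRF trace elements reported as Compton-normalized net intensities.
TRACE_ELEMENT_NAMES = (
    "Al", "Si", "P", "S", "Cl", "K", "Ca", "Mn", "Fe",
    "Ni", "Cu", "Zn", "Br", "Rb", "Sr", "Ba", "Pb",
)

#: Trace elements dropped by default because of pervasive missingness.
DEFAULT_DROP = ("Mn", "Br", "Ba")

#: Non-chemistry columns recognized in sample CSV files.
METADATA_COLUMNS = ("sample_id", "genus", "lon", "lat")


class GridError(ValueError):
    """Raised for invalid or empty study grids."""


@dataclass(frozen=True)
class ChemistryPanel:
    """An ordered set of chemistry variables with their measurement kind.

    Parameters
    ----------
    names
        Unique variable identifiers, e.g. ``"d18O"`` or ``"Sr"``.
    kinds
        One of ``"isotope_ratio"`` or ``"trace_element"`` per variable.
    """

    names: tuple[str, ...]
    kinds: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(set(self.names)):
            raise ValueError("panel variable names must be unique")
        if len(self.names) != len(self.kinds):
            raise ValueError("names and kinds must have equal length")
        bad = set(self.kinds) - {ISOTOPE_RATIO, TRACE_ELEMENT}
        if bad:
            raise ValueError(f"unknown variable kinds: {sorted(bad)}")

    @property
    def m(self) -> int:
        """Number of active variables."""
        return len(self.names)

    def kind_of(self, name: str) -> str:
        return self.kinds[self.names.index(name)]

    @property
    def isotope_names(self) -> tuple[str, ...]:
        return tuple(n for n, k in zip(self.names, self.kinds) if k == ISOTOPE_RATIO)

    @property
    def trace_element_names(self) -> tuple[str, ...]:
        return tuple(n for n, k in zip(self.names, self.kinds) if k == TRACE_ELEMENT)

    def subset(self, names: Sequence[str]) -> "ChemistryPanel":
        """Panel restricted to ``names``, preserving the current order."""
        keep = set(names)
        unknown = keep - set(self.names)
        if unknown:
            raise KeyError(f"unknown panel variables: {sorted(unknown)}")
        pairs = [(n, k) for n, k in zip(self.names, self.kinds) if n in keep]
        return ChemistryPanel(tuple(n for n, _ in pairs), tuple(k for _, k in pairs))


def default_panel() -> ChemistryPanel:
    """The full 23-variable panel: 6 isotope ratios plus 17 trace elements."""
    names = ISOTOPE_NAMES + TRACE_ELEMENT_NAMES
    kinds = (ISOTOPE_RATIO,) * len(ISOTOPE_NAMES) + (TRACE_ELEMENT,) * len(TRACE_ELEMENT_NAMES)
    return ChemistryPanel(names, kinds)


@dataclass
class SampleTable:
    """Georeferenced samples with one chemistry vector per row.

    The backing frame always contains ``sample_id``, ``genus``, ``lon``,
    ``lat``, any number of territory-label columns (e.g. ``country``,
    ``admin1``) and one column per panel variable.  Missing chemistry is
    encoded as NaN; zero is a legal measurement (isotope deltas).
    """

    df: pd.DataFrame
    panel: ChemistryPanel

    def __post_init__(self) -> None:
        for col in METADATA_COLUMNS:
            if col not in self.df.columns:
                raise ValueError(f"sample table missing required column {col!r}")
        for name in self.panel.names:
            if name not in self.df.columns:
                self.df[name] = np.nan
        lon = self.df["lon"].to_numpy(float)
        lat = self.df["lat"].to_numpy(float)
        if np.any((lon < -180) | (lon > 180)) or np.any((lat < -90) | (lat > 90)):
            raise ValueError("coordinates outside valid lon/lat ranges")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def coords(self) -> np.ndarray:
        """(n, 2) array of (lon, lat)."""
        return self.df[["lon", "lat"]].to_numpy(float)

    @property
    def chemistry(self) -> np.ndarray:
        """(n, m) chemistry matrix aligned to the panel; NaN marks missing."""
        return self.df[list(self.panel.names)].to_numpy(float)

    @property
    def label_columns(self) -> list[str]:
        skip = set(METADATA_COLUMNS) | set(self.panel.names)
        return [c for c in self.df.columns if c not in skip]

    def with_panel(self, panel: ChemistryPanel) -> "SampleTable":
        cols = list(METADATA_COLUMNS) + self.label_columns + list(panel.names)
        return SampleTable(self.df[cols].copy(), panel)

    def select(self, mask: np.ndarray) -> "SampleTable":
        return SampleTable(self.df.loc[mask].reset_index(drop=True), self.panel)


def read_samples(path, panel: ChemistryPanel | None = None) -> SampleTable:
    """Read a sample CSV into a :class:`SampleTable`.

    Unknown columns that are neither metadata, known labels nor panel
    variables are reported with a warning and carried through untouched.
    Rows with non-numeric or out-of-range coordinates raise with the
    offending CSV line number (header is line 1).
    """
    panel = panel or default_panel()
    df = pd.read_csv(path, dtype={"sample_id": str, "genus": str})
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample CSV missing required columns: {missing}")
    present_chem = [c for c in panel.names if c in df.columns]
    if not present_chem:
        raise ValueError("sample CSV contains no chemistry columns for the panel")
    known = set(METADATA_COLUMNS) | set(panel.names)
    unknown = [c for c in df.columns if c not in known and c not in ("country", "admin1")]
    if unknown:
        warnings.warn(f"unrecognized columns carried through: {unknown}", stacklevel=2)

    for col in ("lon", "lat"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if df[col].isna().any():
            bad |= df[col].isna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header + 1-based
            raise ValueError(f"non-numeric {col} at CSV line {line}")
        df[col] = vals
    out_of_range = (
        (df["lon"] < -180) | (df["lon"] > 180) | (df["lat"] < -90) | (df["lat"] > 90)
    )
    if out_of_range.any():
        line = int(out_of_range.idxmax()) + 2
        raise ValueError(f"coordinate out of range at CSV line {line}")
    dup = df["sample_id"].duplicated()
    if dup.any():
        raise ValueError(f"duplicate sample_id values: {sorted(df.loc[dup, 'sample_id'].unique())}")
    for c in present_chem:
        df[c] = pd.to_numeric(df[c], errors="coerce")
    sub_panel = panel.subset(present_chem)
    return SampleTable(df, sub_panel)


def write_samples(table: SampleTable, path) -> None:
    """Write a sample table; missing chemistry becomes an empty cell."""
    table.df.to_csv(path, index=False)


@dataclass
class StudyGrid:
    """Regular lon/lat lattice with a boolean genus-range mask.

    Cell centers are generated from the minimum bound in steps of
    ``resolution`` while they remain <= the maximum bound (inclusive
    endpoints up to floating-point slack).
    """

    lon_min: float
    lon_max: float
    lat_min: float
    lat_max: float
    resolution: float
    lons: np.ndarray
    lats: np.ndarray
    mask: np.ndarray  # (n_cells,) bool, row-major lat-outer

    @property
    def n_lon(self) -> int:
        return len(self.lons)

    @property
    def n_lat(self) -> int:
        return len(self.lats)

    @property
    def n_cells(self) -> int:
        return self.n_lon * self.n_lat

    @property
    def cell_lon(self) -> np.ndarray:
        return np.tile(self.lons, self.n_lat)

    @property
    def cell_lat(self) -> np.ndarray:
        return np.repeat(self.lats, self.n_lon)

    @property
    def coords(self) -> np.ndarray:
        """(n_cells, 2) array of (lon, lat) centers in row-major order."""
        return np.column_stack([self.cell_lon, self.cell_lat])

    @property
    def active(self) -> np.ndarray:
        """Indices of masked-in cells, ascending (row-major)."""
        return np.flatnonzero(self.mask)

    @property
    def n_active(self) -> int:
        return int(self.mask.sum())

    def cell_index(self, lon: float, lat: float) -> int:
        """Row-major index of the grid cell nearest to (lon, lat)."""
        k = int(np.clip(np.rint((lon - self.lon_min) / self.resolution), 0, self.n_lon - 1))
        j = int(np.clip(np.rint((lat - self.lat_min) / self.resolution), 0, self.n_lat - 1))
        return j * self.n_lon + k

    def nearest_cells(self, coords: np.ndarray) -> np.ndarray:
        """Vectorized nearest-cell lookup for an (n, 2) lon/lat array."""
        coords = np.atleast_2d(np.asarray(coords, float))
        k = np.clip(np.rint((coords[:, 0] - self.lon_min) / self.resolution), 0, self.n_lon - 1)
        j = np.clip(np.rint((coords[:, 1] - self.lat_min) / self.resolution), 0, self.n_lat - 1)
        return (j * self.n_lon + k).astype(int)


def _axis_centers(vmin: float, vmax: float, res: float) -> np.ndarray:
    n = int(np.floor((vmax - vmin) / res + 1e-9)) + 1
    return vmin + res * np.arange(n)


def build_study_grid(bbox: Sequence[float], resolution: float, range_mask=None) -> StudyGrid:
    """Construct a study grid from a bounding box, resolution and range mask.

    Parameters
    ----------
    bbox
        ``(lon_min, lon_max, lat_min, lat_max)`` in degrees.  A degenerate
        box (min == max) yields a single-row or single-column grid.
    resolution
        Cell spacing in degrees; must be positive.
    range_mask
        ``None`` (all cells active), a boolean array of length ``n_cells``
        in row-major order, or a DataFrame with columns ``lon, lat, flag``:
        each cell is active iff the nearest raster point has a truthy flag.
    """
    if resolution <= 0:
        raise GridError("resolution must be positive")
    lon_min, lon_max, lat_min, lat_max = map(float, bbox)
    if lon_max < lon_min or lat_max < lat_min:
        raise GridError("bounding box maxima must be >= minima")
    lons = _axis_centers(lon_min, lon_max, resolution)
    lats = _axis_centers(lat_min, lat_max, resolution)
    n_cells = len(lons) * len(lats)
    if range_mask is None:
        mask = np.ones(n_cells, dtype=bool)
    elif isinstance(range_mask, pd.DataFrame):
        from scipy.spatial import cKDTree

        pts = range_mask[["lon", "lat"]].to_numpy(float)
        flags = range_mask["flag"].to_numpy()
        tree = cKDTree(pts)
        centers = np.column_stack([np.tile(lons, len(lats)), np.repeat(lats, len(lons))])
        _, idx = tree.query(centers)
        mask = flags[idx].astype(bool)
    else:
        mask = np.asarray(range_mask, dtype=bool)
        if mask.shape != (n_cells,):
            raise GridError(f"mask length {mask.shape} does not match grid size {n_cells}")
        mask = mask.copy()
    if not mask.any():
        raise GridError("all grid cells are masked out (empty grid)")
    return StudyGrid(lon_min, lon_max, lat_min, lat_max, float(resolution), lons, lats, mask)


def write_grid_csv(grid: StudyGrid, path) -> None:
    pd.DataFrame(
        {"lon": grid.cell_lon, "lat": grid.cell_lat, "flag": grid.mask.astype(int)}
    ).to_csv(path, index=False)


def read_grid_csv(path, bbox, resolution) -> StudyGrid:
    df = pd.read_csv(path)
    return build_study_grid(bbox, resolution, df)


@dataclass
class RegionSet:
    """Named territories as disjoint sets of masked-in grid-cell indices."""

    scale: str
    regions: dict[str, np.ndarray]
    provenance: str = "tiling"

    def validate(self, grid: StudyGrid) -> None:
        active = set(grid.active.tolist())
        seen: dict[int, str] = {}
        for rid, cells in self.regions.items():
            for c in np.asarray(cells).tolist():
                if c not in active:
                    raise ValueError(f"region {rid!r} references masked-out cell {c}")
                if c in seen:
                    raise ValueError(f"cell {c} assigned to both {seen[c]!r} and {rid!r}")
                seen[c] = rid

    def region_of(self, cell: int) -> str | None:
        for rid, cells in self.regions.items():
            if cell in cells:
                return rid
        return None

    @property
    def ids(self) -> list[str]:
        return list(self.regions)


def regions_from_polygons(grid: StudyGrid, geojson, scale: str = "custom") -> RegionSet:
    """Build territories from a GeoJSON FeatureCollection of polygons.

    A cell belongs to a territory iff its center lies inside (or on the
    boundary of) the polygon carrying that ``territory_id``.  Polygons whose
    interiors overlap within one scale are rejected.  A boundary center
    covered by two adjacent polygons goes to the earlier feature.
    """
    if isinstance(geojson, (str, bytes)) or hasattr(geojson, "read"):
        if hasattr(geojson, "read"):
            gj = json.load(geojson)
        else:
            with open(geojson) as fh:
                gj = json.load(fh)
    else:
        gj = geojson
    feats = gj["features"] if gj.get("type") == "FeatureCollection" else [gj]
    polys: list[tuple[str, object]] = []
    for f in feats:
        props = f.get("properties") or {}
        tid = props.get("territory_id")
        if tid is None:
            raise ValueError("feature missing 'territory_id' property")
        geom = shapely_shape(f["geometry"])
        if not geom.is_valid:
            raise ValueError(f"invalid polygon for territory {tid!r}")
        polys.append((str(tid), geom))
    for i in range(len(polys)):
        for j in range(i + 1, len(polys)):
            inter = polys[i][1].intersection(polys[j][1])
            if inter.area > 1e-10:
                raise ValueError(
                    f"overlapping polygons at one scale: {polys[i][0]!r} and {polys[j][0]!r}"
                )
    active = grid.active
    pts = shapely.points(grid.coords[active])
    assigned = np.full(len(active), -1)
    regions: dict[str, np.ndarray] = {}
    for pi, (tid, geom) in enumerate(polys):
        inside = shapely.covers(geom, pts)
        take = inside & (assigned < 0)
        assigned[take] = pi
        cells = active[take]
        if len(cells) == 0:
            warnings.warn(f"territory {tid!r} contains no grid cells", stacklevel=2)
        regions[tid] = cells
    return RegionSet(scale=scale, regions=regions, provenance="polygon")


def tile_regions(grid: StudyGrid, tile_size: float, scale: str | None = None) -> RegionSet:
    """Partition masked cells into square tiles anchored at (0 deg, 0 deg).

    A cell center (lon, lat) falls in the half-open tile
    ``[i*t, (i+1)*t) x [j*t, (j+1)*t)`` with ``i = floor(lon/t)``,
    ``j = floor(lat/t)``.
    """
    if tile_size <= 0:
        raise ValueError("tile_size must be positive")
    active = grid.active
    lon = grid.cell_lon[active]
    lat = grid.cell_lat[active]
    ti = np.floor(np.round(lon / tile_size, 9)).astype(int)
    tj = np.floor(np.round(lat / tile_size, 9)).astype(int)
    regions: dict[str, np.ndarray] = {}
    for i, j in sorted(set(zip(ti.tolist(), tj.tolist()))):
        sel = (ti == i) & (tj == j)
        regions[f"tile{tile_size:g}_{i}_{j}"] = active[sel]
    return RegionSet(scale=scale or f"tile_{tile_size:g}", regions=regions, provenance="tiling")


def regions_from_labels(grid: StudyGrid, table: SampleTable, label: str) -> RegionSet:
    """Voronoi-style territories induced by labelled samples: each masked cell
    joins the territory of the nearest labelled sample (haversine)."""
    from .determine import great_circle_km

    labels = table.df[label].astype(str).to_numpy()
    coords = table.coords
    active = grid.active
    centers = grid.coords[active]
    best = np.full(len(active), -1)
    best_d = np.full(len(active), np.inf)
    for i in range(len(coords)):
        d = great_circle_km(centers, coords[i])
        closer = d < best_d
        best_d[closer] = d[closer]
        best[closer] = i
    regions: dict[str, np.ndarray] = {}
    for lab in sorted(set(labels.tolist())):
        sel = np.isin(best, np.flatnonzero(labels == lab))
        regions[lab] = active[sel]
    return RegionSet(scale=label, regions=regions, provenance="tiling")
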