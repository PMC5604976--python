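"""Regular lon/lat grid geometry, point rasterization and proximity transforms.

The analysis grid is an unprojected geographic grid (EPSG:4326) with square
cells in degrees — by default 1/120 degree, roughly 1 km at mid-latitudes.
Rows run north to south (row 0 is the northernmost row), columns west to
east, and cells are half-open intervals ``[edge, edge + resolution)`` so a
point on a shared edge belongs to the cell to its east/south.

Three information-capacity transforms of a set of occurrence points live
here: ``rasterize_count`` (number of sites per cell), ``to_presence``
(count collapsed to 0/1) and ``distance_to_nearest`` (great-circle distance
in meters from every cell center to the closest site).
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

logger = logging.getLogger("hpvsdm")

#: Mean Earth radius in meters (IUGG), used by every great-circle distance here.
EARTH_RADIUS_M = 6_371_008.8

#: Default nodata sentinel for float rasters.
DEFAULT_NODATA = -9999.0


class OutOfDomainError(ValueError):
    """A point falls outside the grid extent."""


@dataclass(frozen=True)
class GridSpec:
    """Definition of a regular lon/lat grid.

    Parameters
    ----------
    xmin, ymin, xmax, ymax
        Extent in degrees longitude/latitude.
    resolution
        Cell size in degrees (same in both axes). Default 1/120 degree.
    """

    xmin: float
    ymin: float
    xmax: float
    ymax: float
    resolution: float = 1.0 / 120.0

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError(f"resolution must be positive, got {self.resolution}")
        if not (self.xmax > self.xmin and self.ymax > self.ymin):
            raise ValueError("grid extent must satisfy xmax > xmin and ymax > ymin")

    @property
    def ncols(self) -> int:
        return int(round((self.xmax - self.xmin) / self.resolution))

    @property
    def nrows(self) -> int:
        return int(round((self.ymax - self.ymin) / self.resolution))

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    @classmethod
    def from_origin(cls, xmin: float, ymin: float, nrows: int, ncols: int,
                    resolution: float = 1.0 / 120.0) -> "GridSpec":
        """Build a grid from its south-west corner and cell counts."""
        return cls(xmin, ymin, xmin + ncols * resolution, ymin + nrows * resolution,
                   resolution)

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """(lon, lat) of a cell center; row 0 is the northern edge."""
        lon = self.xmin + (col + 0.5) * self.resolution
        lat = self.ymax - (row + 0.5) * self.resolution
        return lon, lat

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays (lon[ncols], lat[nrows]) of all center coordinates."""
        cols = np.arange(self.ncols)
        rows = np.arange(self.nrows)
        lons = self.xmin + (cols + 0.5) * self.resolution
        lats = self.ymax - (rows + 0.5) * self.resolution
        return lons, lats


@dataclass
class RasterLayer:
    """A single named band of values over a :class:`GridSpec`.

    ``values`` is an ``nrows x ncols`` array; ``nodata`` is the sentinel for
    missing cells (compared with equality, so prefer a value outside the
    data range).
    """

    grid: GridSpec
    name: str
    values: np.ndarray
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"layer {self.name!r}: values shape {self.values.shape} does not "
                f"match grid shape {self.grid.shape}"
            )

    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds valid data."""
        return self.values != self.nodata

    def copy(self, name: str | None = None,
             values: np.ndarray | None = None) -> "RasterLayer":
        return RasterLayer(
            self.grid,
            self.name if name is None else name,
            self.values.copy() if values is None else np.asarray(values),
            self.nodata,
        )


# ---------------------------------------------------------------------------
# Point → cell geometry
# ---------------------------------------------------------------------------

def cell_of(lon: float, lat: float, grid: GridSpec) -> tuple[int, int]:
    """Return the 0-based (row, col) of the cell containing a point.

    Cells are half-open: ``col = floor((lon - xmin)/res)`` and rows count
    from the north, ``row = floor((ymax - lat)/res)``. Points outside the
    extent raise :class:`OutOfDomainError`.
    """
    rows, cols = cells_of(np.asarray([lon], float), np.asarray([lat], float), grid)
    return int(rows[0]), int(cols[0])


def cells_of(lons: np.ndarray, lats: np.ndarray, grid: GridSpec,
             drop_outside: bool = False
             ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized :func:`cell_of`.

    With ``drop_outside`` the out-of-extent points are removed with a logged
    count instead of raising.
    """
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    inside = (
        (lons >= grid.xmin) & (lons < grid.xmax)
        & (lats > grid.ymin) & (lats <= grid.ymax)
    )
    if not inside.all():
        if not drop_outside:
            bad = np.flatnonzero(~inside)[0]
            raise OutOfDomainError(
                f"point (lon={lons[bad]}, lat={lats[bad]}) outside grid extent "
                f"[{grid.xmin}, {grid.xmax}) x ({grid.ymin}, {grid.ymax}]"
            )
        logger.warning("dropping %d point(s) outside grid extent", (~inside).sum())
        lons, lats = lons[inside], lats[inside]
    cols = np.floor((lons - grid.xmin) / grid.resolution).astype(int)
    rows = np.floor((grid.ymax - lats) / grid.resolution).astype(int)
    # points exactly on the north/west boundary belong to the edge cell
    cols = np.clip(cols, 0, grid.ncols - 1)
    rows = np.clip(rows, 0, grid.nrows - 1)
    return rows, cols


def rasterize_count(points: np.ndarray, grid: GridSpec,
                    drop_outside: bool = False, name: str = "count") -> RasterLayer:
    """Count of points per cell. ``points`` is an (n, 2) array of lon/lat.

    The sum over all cells equals the number of retained points; an empty
    point set yields an all-zero layer.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    values = np.zeros(grid.shape, dtype=np.int32)
    if len(points):
        rows, cols = cells_of(points[:, 0], points[:, 1], grid, drop_outside)
        np.add.at(values, (rows, cols), 1)
    return RasterLayer(grid, name, values, nodata=-1)


def to_presence(count_layer: RasterLayer, name: str | None = None) -> RasterLayer:
    """Collapse a count layer to presence/absence (1 where count > 0)."""
    values = count_layer.values
    valid = count_layer.mask()
    if (values[valid] < 0).any():
        raise ValueError("count layer contains negative values")
    out = np.where(valid, (values > 0).astype(np.int32), count_layer.nodata)
    return RasterLayer(count_layer.grid, name or "presence",
                       out.astype(values.dtype), count_layer.nodata)


# ---------------------------------------------------------------------------
# Distance transform
# ---------------------------------------------------------------------------

def haversine_m(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in meters between lon/lat pairs (degrees)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float))
                              for a in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def _unit_sphere(lons: np.ndarray, lats: np.ndarray) -> np.ndarray:
    lam = np.radians(lons)
    phi = np.radians(lats)
    return np.column_stack(
        (np.cos(phi) * np.cos(lam), np.cos(phi) * np.sin(lam), np.sin(phi))
    )


def distance_to_nearest(points: np.ndarray, grid: GridSpec,
                        name: str = "distance") -> RasterLayer:
    """Great-circle distance (m) from every cell center to the nearest point.

    The nearest neighbour is found on the unit sphere with a k-d tree (chord
    distance is monotone in great-circle distance, so the chord-nearest point
    is also the arc-nearest) and converted back to an arc length on a sphere
    of radius :data:`EARTH_RADIUS_M`. Raises on an empty point set — a
    distance to nothing is undefined.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(points) == 0:
        raise ValueError("distance_to_nearest requires at least one point")
    lons, lats = grid.cell_centers()
    glon, glat = np.meshgrid(lons, lats)
    centers = _unit_sphere(glon.ravel(), glat.ravel())
    tree = cKDTree(_unit_sphere(points[:, 0], points[:, 1]))
    chord, _ = tree.query(centers, k=1)
    arc = 2.0 * np.arcsin(np.clip(chord / 2.0, 0.0, 1.0))
    values = (EARTH_RADIUS_M * arc).reshape(grid.shape)
    return RasterLayer(grid, name, values)


# ---------------------------------------------------------------------------
# Raster and point I/O (plain-text formats)
# ---------------------------------------------------------------------------

def write_ascii_grid(layer: RasterLayer, path) -> None:
    """Write a layer as an ESRI ASCII grid (.asc), north row first."""
    g = layer.grid
    with open(path, "w") as fh:
        fh.write(f"ncols {g.ncols}\n")
        fh.write(f"nrows {g.nrows}\n")
        fh.write(f"xllcorner {g.xmin!r}\n")
        fh.write(f"yllcorner {g.ymin!r}\n")
        fh.write(f"cellsize {g.resolution!r}\n")
        fh.write(f"NODATA_value {layer.nodata!r}\n")
        np.savetxt(fh, np.asarray(layer.values, dtype=float), fmt="%.10g")


def read_ascii_grid(path, name: str | None = None) -> RasterLayer:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`."""
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh)
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    grid = GridSpec.from_origin(header["xllcorner"], header["yllcorner"],
                                nrows, ncols, header["cellsize"])
    values = np.asarray(values, dtype=float).reshape(nrows, ncols)
    import os
    label = name or os.path.splitext(os.path.basename(str(path)))[0]
    return RasterLayer(grid, label, values, header.get("nodata_value", DEFAULT_NODATA))


def write_points_csv(path, lons, lats, onset_year=None, census_year=None,
                     ids=None) -> None:
    """Write points (and optional onset/census years) to CSV."""
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    cols = ["lon", "lat"]
    if onset_year is not None:
        cols.append("onset_year")
    if census_year is not None:
        cols.append("census_year")
    if ids is not None:
        cols.append("id")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(cols)
        for i in range(len(lons)):
            row: list = [repr(float(lons[i])), repr(float(lats[i]))]
            if onset_year is not None:
                row.append(int(onset_year[i]))
            if census_year is not None:
                row.append(int(census_year[i]))
            if ids is not None:
                row.append(ids[i])
            writer.writerow(row)


def read_points_csv(path) -> dict[str, np.ndarray]:
    """Read a points CSV into a dict of column arrays (lon/lat as float)."""
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        rows = list(reader)
    out: dict[str, np.ndarray] = {}
    if not rows:
        return {"lon": np.empty(0), "lat": np.empty(0)}
    for key in rows[0]:
        col = [r[key] for r in rows]
        if key in ("lon", "lat"):
            out[key] = np.asarray(col, dtype=float)
        elif key in ("onset_year", "census_year"):
            out[key] = np.asarray(col, dtype=int)
        else:
            out[key] = np.asarray(col)
    return out


def points_to_geojson(lons, lats, properties: list[dict] | None = None) -> dict:
    """Build a GeoJSON FeatureCollection of Point features."""
    features = []
    for i in range(len(lons)):
        props = properties[i] if properties is not None else {}
        features.append({
            "type": "Feature",
            "geometry": {"type": "Point",
                         "coordinates": [float(lons[i]), float(lats[i])]},
            "properties": props,
        })
    return {"type": "FeatureCollection", "features": features}


def geojson_to_points(obj: dict) -> tuple[np.ndarray, list[dict]]:
    """Extract an (n, 2) lon/lat array and property dicts from GeoJSON."""
    coords, props = [], []
    for feat in obj.get("features", []):
        geom = feat.get("geometry") or {}
        if geom.get("type") != "Point":
            continue
        coords.append(geom["coordinates"][:2])
        props.append(feat.get("properties") or {})
    return np.asarray(coords, dtype=float).reshape(-1, 2), props


def write_geojson(path, obj: dict) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh)


def read_geojson(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
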