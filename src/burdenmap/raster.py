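"""Georeferenced grids and the raster operators the mapping pipeline needs.

Conventions, stated once and used everywhere:

* cell-center registration — ``(col, row)`` maps to the *center* of a cell;
* row 0 is the northernmost row, columns increase eastward;
* nodata is carried as ``NaN`` in memory and as an explicit sentinel on disk;
* two coordinate systems are supported: ``"EPSG:4326"`` (lon/lat decimal
  degrees, distances by great circle with per-row cos-latitude scaling) and
  ``"km"`` (planar kilometres, for exact unit tests and toy problems).

Rasters are exchanged as ESRI ASCII grids (a plain-text format readable by
GDAL and the R ``raster`` package); zone polygons as GeoJSON.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from shapely.geometry import mapping as shapely_mapping, shape

# mean degree lengths (km) at the equator; longitude scaled by cos(lat)
KM_PER_DEG_LAT = 110.574
KM_PER_DEG_LON = 111.320

EARTH_RADIUS_KM = 6371.0088


@dataclass(frozen=True)
class GridTransform:
    """Affine map from (col, row) to map coordinates of cell centers.

    ``west``/``north`` are the outer edges of the grid; ``dx``/``dy`` the
    positive cell sizes.  Center of (col, row) is
    ``(west + (col + 0.5) dx, north - (row + 0.5) dy)``.
    """

    west: float
    north: float
    dx: float
    dy: float

    def __post_init__(self) -> None:
        if self.dx <= 0 or self.dy <= 0:
            raise ValueError("cell sizes must be positive")

    def xy(self, col, row):
        return (
            self.west + (np.asarray(col) + 0.5) * self.dx,
            self.north - (np.asarray(row) + 0.5) * self.dy,
        )

    def colrow(self, x, y):
        """Fractional (col, row) of a map coordinate, center-registered."""
        return (
            (np.asarray(x) - self.west) / self.dx - 0.5,
            (self.north - np.asarray(y)) / self.dy - 0.5,
        )


@dataclass
class Grid:
    """A single-band raster: 2-D float values with an affine transform.

    ``values`` uses NaN for nodata; ``nodata`` is only the on-disk sentinel.
    """

    values: np.ndarray
    transform: GridTransform
    crs: str = "EPSG:4326"
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("Grid values must be 2-D")

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def mask(self) -> np.ndarray:
        """True where data is valid."""
        return np.isfinite(self.values)

    def center_coords(self):
        """(X, Y) arrays of every cell center, each shaped like ``values``."""
        cols = np.arange(self.width)
        rows = np.arange(self.height)
        x, _ = self.transform.xy(cols, 0)
        _, y = self.transform.xy(0, rows)
        return np.meshgrid(x, y)

    def index_of(self, x: float, y: float) -> tuple[int, int]:
        """(row, col) of the cell containing a point; raises if outside."""
        col = int(math.floor((x - self.transform.west) / self.transform.dx))
        row = int(math.floor((self.transform.north - y) / self.transform.dy))
        if not (0 <= row < self.height and 0 <= col < self.width):
            raise ValueError(f"point ({x}, {y}) outside grid extent")
        return row, col

    def sample_nearest(self, xs, ys) -> np.ndarray:
        """Values at the cells containing the given points (NaN outside)."""
        xs = np.atleast_1d(np.asarray(xs, dtype=float))
        ys = np.atleast_1d(np.asarray(ys, dtype=float))
        col = np.floor((xs - self.transform.west) / self.transform.dx).astype(int)
        row = np.floor((self.transform.north - ys) / self.transform.dy).astype(int)
        out = np.full(xs.shape, np.nan)
        ok = (row >= 0) & (row < self.height) & (col >= 0) & (col < self.width)
        out[ok] = self.values[row[ok], col[ok]]
        return out

    def copy_with(self, values: np.ndarray) -> "Grid":
        if values.shape != self.values.shape:
            raise ValueError("shape mismatch")
        return Grid(values, self.transform, self.crs, self.nodata)


@dataclass
class CovariateStack:
    """Named grids sharing one geometry and one nodata mask."""

    grids: dict[str, Grid] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.grids:
            raise ValueError("CovariateStack needs at least one grid")
        ref = next(iter(self.grids.values()))
        for name, g in self.grids.items():
            if g.values.shape != ref.values.shape or g.transform != ref.transform:
                raise ValueError(f"grid {name!r} not aligned with the stack")
            if g.crs != ref.crs:
                raise ValueError(f"grid {name!r} has a different crs")

    @property
    def template(self) -> Grid:
        return next(iter(self.grids.values()))

    @property
    def names(self) -> list[str]:
        return list(self.grids)

    def __getitem__(self, name: str) -> Grid:
        return self.grids[name]

    def sample(self, names: Sequence[str], xs, ys) -> np.ndarray:
        """Design matrix of covariate values at points, shape (n_points, len(names))."""
        return np.column_stack([self.grids[n].sample_nearest(xs, ys) for n in names])


def great_circle_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Haversine distance in km (broadcasting)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float)) for a in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def point_distance_km(crs: str, lon1, lat1, lon2, lat2) -> np.ndarray:
    if crs == "km":
        return np.hypot(np.asarray(lon2) - lon1, np.asarray(lat2) - lat1)
    return great_circle_km(lon1, lat1, lon2, lat2)


def resample_bilinear(src: Grid, template: Grid) -> Grid:
    """Resample ``src`` onto ``template``'s geometry by bilinear interpolation.

    Each output cell interpolates the 4 source cell centers surrounding its
    center.  Corners that carry zero weight do not contribute, so resampling a
    grid onto its own geometry is the identity.  Any positively weighted
    nodata corner makes the output cell nodata; cells outside the source's
    center lattice are nodata.
    """
    if src.crs != template.crs:
        raise ValueError("crs mismatch between source and template")
    X, Y = template.center_coords()
    u, v = src.transform.colrow(X, Y)  # fractional col/row into src centers
    eps = 1e-9  # tolerate float round-off at the outermost cell centers
    inside = (u >= -eps) & (u <= src.width - 1 + eps) & \
             (v >= -eps) & (v <= src.height - 1 + eps)
    if not inside.any():
        raise ValueError("template extent disjoint from source center lattice")

    u = np.clip(u, 0, src.width - 1)
    v = np.clip(v, 0, src.height - 1)
    c0 = np.clip(np.floor(u).astype(int), 0, src.width - 2) if src.width > 1 else np.zeros_like(u, int)
    r0 = np.clip(np.floor(v).astype(int), 0, src.height - 2) if src.height > 1 else np.zeros_like(v, int)
    c1 = np.minimum(c0 + 1, src.width - 1)
    r1 = np.minimum(r0 + 1, src.height - 1)
    fu = u - c0
    fv = v - r0

    out = np.zeros_like(u, dtype=float)
    bad = np.zeros_like(u, dtype=bool)
    corners = (
        (r0, c0, (1 - fu) * (1 - fv)),
        (r0, c1, fu * (1 - fv)),
        (r1, c0, (1 - fu) * fv),
        (r1, c1, fu * fv),
    )
    for rr, cc, w in corners:
        vals = src.values[rr, cc]
        active = w > 0
        bad |= active & ~np.isfinite(vals)
        out += np.where(active, w * np.where(np.isfinite(vals), vals, 0.0), 0.0)
    out[bad | ~inside] = np.nan
    return Grid(out, template.transform, template.crs, template.nodata)


def classify_urbanicity(pop: Grid, urban_density: float = 1000.0,
                        peri_density: float = 250.0, peri_km: float = 15.0) -> Grid:
    """Classify population density into urban (2), peri-urban (1), rural (0).

    Urban: density >= 1000 persons/km².  Peri-urban: density > 250 and within
    15 km of the nearest urban cell center, not itself urban.  Rural is the
    complement.  Nodata propagates.
    """
    d = pop.values
    if np.nanmin(d) < 0:
        raise ValueError("population density must be non-negative")
    out = np.zeros_like(d)
    urban = d >= urban_density
    out[urban] = 2.0
    cand = (d > peri_density) & ~urban & np.isfinite(d)
    if urban.any() and cand.any():
        X, Y = pop.center_coords()
        ux, uy = X[urban], Y[urban]
        cx, cy = X[cand], Y[cand]
        near = np.zeros(cx.size, dtype=bool)
        step = max(1, 2_000_000 // max(ux.size, 1))
        for start in range(0, cx.size, step):
            sl = slice(start, start + step)
            dist = point_distance_km(
                pop.crs, cx[sl][:, None], cy[sl][:, None], ux[None, :], uy[None, :]
            )
            near[sl] = (dist <= peri_km).any(axis=1)
        idx = np.flatnonzero(cand.ravel())[near]
        out.ravel()[idx] = 1.0
    out[~np.isfinite(d)] = np.nan
    return pop.copy_with(out)


def _edge_lengths_km(grid: Grid):
    """Per-row horizontal, vertical, and diagonal inter-center distances (km)."""
    rows = np.arange(grid.height)
    _, lat = grid.transform.xy(0, rows)
    if grid.crs == "km":
        ew = np.full(grid.height, grid.transform.dx)
        ns = grid.transform.dy
        diag = np.full(grid.height - 1, math.hypot(grid.transform.dx, grid.transform.dy))
        return ew, ns, diag
    ew = KM_PER_DEG_LON * np.cos(np.radians(lat)) * grid.transform.dx
    ns = KM_PER_DEG_LAT * grid.transform.dy
    midlat = (lat[:-1] + lat[1:]) / 2 if grid.height > 1 else np.array([])
    diag = np.sqrt(
        (KM_PER_DEG_LON * np.cos(np.radians(midlat)) * grid.transform.dx) ** 2 + ns**2
    )
    return ew, ns, diag


def cost_distance(friction: Grid, sources: Sequence[tuple[float, float]]) -> Grid:
    """Multi-source least-cost travel time over the 8-connected cell graph.

    ``friction`` is in minutes per km.  The cost of traversing an edge is the
    mean of the two cells' friction times the inter-center distance in km
    (diagonal steps use the diagonal distance).  Source cells cost 0.
    """
    vals = friction.values
    finite = np.isfinite(vals)
    if np.any(finite & (vals <= 0)):
        raise ValueError("friction must be strictly positive where not nodata")
    h, w = vals.shape
    node = np.arange(h * w).reshape(h, w)
    ew, ns, diag = _edge_lengths_km(friction)

    rows_i, cols_i, weights = [], [], []

    def add_edges(a_idx, b_idx, fric_a, fric_b, length):
        ok = np.isfinite(fric_a) & np.isfinite(fric_b)
        rows_i.append(a_idx[ok])
        cols_i.append(b_idx[ok])
        weights.append(((fric_a[ok] + fric_b[ok]) / 2) * np.broadcast_to(length, fric_a.shape)[ok])

    if w > 1:  # horizontal
        add_edges(node[:, :-1].ravel(), node[:, 1:].ravel(),
                  vals[:, :-1].ravel(), vals[:, 1:].ravel(),
                  np.repeat(ew, w - 1))
    if h > 1:  # vertical
        add_edges(node[:-1, :].ravel(), node[1:, :].ravel(),
                  vals[:-1, :].ravel(), vals[1:, :].ravel(),
                  np.full((h - 1) * w, ns) if friction.crs == "km" else np.full((h - 1) * w, ns))
    if h > 1 and w > 1:  # diagonals
        add_edges(node[:-1, :-1].ravel(), node[1:, 1:].ravel(),
                  vals[:-1, :-1].ravel(), vals[1:, 1:].ravel(),
                  np.repeat(diag, w - 1))
        add_edges(node[:-1, 1:].ravel(), node[1:, :-1].ravel(),
                  vals[:-1, 1:].ravel(), vals[1:, :-1].ravel(),
                  np.repeat(diag, w - 1))

    src_nodes = []
    for lon, lat in sources:
        try:
            r, c = friction.index_of(lon, lat)
        except ValueError:
            continue
        if finite[r, c]:
            src_nodes.append(node[r, c])
    if not src_nodes:
        raise ValueError("no source falls inside the grid's valid extent")

    n = h * w
    if rows_i:
        i = np.concatenate(rows_i)
        j = np.concatenate(cols_i)
        wgt = np.concatenate(weights)
        graph = coo_matrix((wgt, (i, j)), shape=(n, n)).tocsr()
    else:
        graph = coo_matrix((n, n)).tocsr()
    dist = dijkstra(graph, directed=False, indices=src_nodes, min_only=True)
    dist = dist.reshape(h, w)
    dist[~finite] = np.nan
    dist[np.isinf(dist)] = np.nan
    return friction.copy_with(dist)


def align_stack(grids: Mapping[str, Grid], template: Grid) -> CovariateStack:
    """Resample every grid to the template and apply the union nodata mask."""
    if not grids:
        raise ValueError("align_stack needs at least one grid")
    resampled = {name: resample_bilinear(g, template) for name, g in grids.items()}
    joint = np.ones(template.values.shape, dtype=bool)
    for g in resampled.values():
        joint &= g.mask
    for g in resampled.values():
        g.values[~joint] = np.nan
    return CovariateStack(resampled)


# --------------------------------------------------------------------------
# Plain-text I/O: ESRI ASCII grids and GeoJSON zones

def write_ascii_grid(grid: Grid, path: str | Path) -> None:
    """Write as an ESRI ASCII grid (requires square cells)."""
    if not math.isclose(grid.transform.dx, grid.transform.dy, rel_tol=1e-9):
        raise ValueError("ESRI ASCII grids require dx == dy")
    t = grid.transform
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    vals = np.where(grid.mask, grid.values, grid.nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.width}\n")
        fh.write(f"nrows {grid.height}\n")
        fh.write(f"xllcorner {t.west!r}\n")
        fh.write(f"yllcorner {t.north - grid.height * t.dy!r}\n")
        fh.write(f"cellsize {t.dx!r}\n")
        fh.write(f"NODATA_value {grid.nodata!r}\n")
        for row in vals:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")
    Path(str(path) + ".crs").write_text(grid.crs + "\n")


def read_ascii_grid(path: str | Path) -> Grid:
    path = Path(path)
    with open(path) as fh:
        header: dict[str, float] = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh)
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    data = data.reshape(nrows, ncols)
    nodata = header.get("nodata_value", -9999.0)
    data[data == nodata] = np.nan
    cell = header["cellsize"]
    transform = GridTransform(
        west=header["xllcorner"],
        north=header["yllcorner"] + nrows * cell,
        dx=cell,
        dy=cell,
    )
    crs_path = Path(str(path) + ".crs")
    crs = crs_path.read_text().strip() if crs_path.exists() else "EPSG:4326"
    return Grid(data, transform, crs, nodata)


def read_zones(path: str | Path) -> list[tuple[str, object]]:
    """Read (zone_id, shapely geometry) pairs from a GeoJSON FeatureCollection."""
    with open(path) as fh:
        gj = json.load(fh)
    zones = []
    for i, feat in enumerate(gj.get("features", [])):
        props = feat.get("properties") or {}
        zid = str(props.get("id", props.get("zone_id", i)))
        zones.append((zid, shape(feat["geometry"])))
    return zones


def write_zones(zones: Iterable[tuple[str, object]], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    features = [
        {
            "type": "Feature",
            "properties": {"id": zid},
            "geometry": shapely_mapping(geom),
        }
        for zid, geom in zones
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def zone_id_grid(template: Grid, zones: Sequence[tuple[str, object]]) -> np.ndarray:
    """Object array of zone ids by cell-center containment (None where uncovered).

    Later zones in the list do not overwrite earlier ones where polygons
    overlap, making assignment deterministic.
    """
    from shapely import contains_xy

    X, Y = template.center_coords()
    out = np.full(template.values.shape, None, dtype=object)
    unassigned = np.ones(template.values.shape, dtype=bool)
    for zid, geom in zones:
        hit = unassigned & contains_xy(geom, X, Y)
        out[hit] = zid
        unassigned &= ~hit
    return out
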