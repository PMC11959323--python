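"""Grid/raster/vector data model, standard-format I/O, and polygon-to-cell resolution.

The analysis operates on three co-registered single-band rasters sharing one
planar equal-area grid:

* ``year``     -- per-cell disturbance year (int16), 0 = undisturbed;
* ``severity`` -- per-cell canopy-loss index in [0, 1] (float32), -1 = nodata;
* ``forest``   -- binary forest mask (uint8).

Polygon layers of documented and potential primary forests are carried as
shapely geometries with stratum attributes (country, biogeographical region,
EU membership) plus a dataset table holding each dataset's status and mapping
year.  Rasters are GeoTIFFs (ModelPixelScale / ModelTiepoint tags); polygons
are GeoJSON; tables are CSV.

Grid convention: 0-based (row, col), row 0 at the top (north); ``origin`` is
the map coordinate of the grid's top-left corner.  Cell (r, c) has its center
at ``(x0 + (c + 0.5) s, y0 - (r + 0.5) s)`` for cell size ``s``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import mapping as geom_mapping, shape as geom_shape
from shapely.geometry.base import BaseGeometry

#: Sentinel in the year raster for never-disturbed cells.
UNDISTURBED = 0
#: Sentinel in the severity raster for cells without a valid severity.
SEV_NODATA = -1.0

DOCUMENTED = "documented"
POTENTIAL = "potential"

# GeoTIFF tag codes.
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922


class GeodataError(ValueError):
    """Raised on invalid grids, geometries, or co-registration failures."""


@dataclass(frozen=True)
class Grid:
    """A square-celled planar grid in an equal-area projection.

    Parameters
    ----------
    nrows, ncols
        Raster dimensions (>= 1).
    cell_size
        Cell edge length in meters (> 0); cells are square, so the cell area
        is ``cell_size ** 2``.
    origin
        Map coordinate ``(x0, y0)`` of the top-left grid corner.
    crs_tag
        Free-text CRS label; expected to denote an equal-area projection
        (areas are computed as cell counts times the cell area).
    """

    nrows: int
    ncols: int
    cell_size: float = 30.0
    origin: tuple[float, float] = (0.0, 0.0)
    crs_tag: str = "synthetic-equal-area"

    def __post_init__(self) -> None:
        if self.nrows < 1 or self.ncols < 1:
            raise GeodataError(f"grid must be at least 1x1, got {self.nrows}x{self.ncols}")
        if not self.cell_size > 0:
            raise GeodataError(f"cell_size must be positive, got {self.cell_size}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    def cell_center(self, row: np.ndarray | int, col: np.ndarray | int) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates of cell centers (vectorized)."""
        x0, y0 = self.origin
        x = x0 + (np.asarray(col) + 0.5) * self.cell_size
        y = y0 - (np.asarray(row) + 0.5) * self.cell_size
        return x, y


def cell_area_ha(grid: Grid) -> float:
    """Area of one grid cell in hectares (``cell_size**2 / 10_000``)."""
    return grid.cell_size**2 / 10_000.0


@dataclass
class DisturbanceLayers:
    """The three co-registered rasters plus the analysis window.

    ``year`` holds the disturbance year per cell (``UNDISTURBED`` = 0 for
    never-disturbed cells), valid within ``[year_min, year_max]``.
    ``severity`` holds a canopy-loss index in [0, 1] (``SEV_NODATA`` < 0 where
    undefined) and is only considered valid for disturbance years up to
    ``severity_year_max``.
    """

    grid: Grid
    year: np.ndarray
    severity: np.ndarray
    forest: np.ndarray
    year_min: int = 1986
    year_max: int = 2020
    severity_year_max: int = 2016

    def __post_init__(self) -> None:
        self.year = np.asarray(self.year, dtype=np.int16)
        self.severity = np.asarray(self.severity, dtype=np.float32)
        self.forest = np.asarray(self.forest, dtype=bool)
        self.validate()

    def validate(self) -> None:
        for name, arr in (("year", self.year), ("severity", self.severity), ("forest", self.forest)):
            if arr.shape != self.grid.shape:
                raise GeodataError(
                    f"{name} layer shape {arr.shape} does not match grid {self.grid.shape}"
                )
        yr = self.year
        bad = (yr != UNDISTURBED) & ((yr < self.year_min) | (yr > self.year_max))
        if bad.any():
            raise GeodataError(
                f"{int(bad.sum())} year value(s) outside [{self.year_min}, {self.year_max}]"
            )
        sev = self.severity
        bad = (sev > 1.0) | ((sev < 0.0) & (sev != np.float32(SEV_NODATA)))
        if bad.any():
            raise GeodataError(
                f"{int(bad.sum())} severity value(s) outside [0, 1] (nodata sentinel is {SEV_NODATA})"
            )

    @property
    def n_years(self) -> int:
        return self.year_max - self.year_min + 1


@dataclass(frozen=True)
class PolygonDataset:
    """A source dataset of primary-forest polygons.

    Documented datasets carry the year they were surveyed (the *mapping
    year*); potential datasets have none and are assessed over the full
    disturbance window.
    """

    dataset_id: str
    status: str
    mapping_year: int | None = None

    def __post_init__(self) -> None:
        if self.status not in (DOCUMENTED, POTENTIAL):
            raise GeodataError(f"unknown dataset status {self.status!r}")
        if self.status == DOCUMENTED and self.mapping_year is None:
            raise GeodataError(f"documented dataset {self.dataset_id!r} requires a mapping_year")
        if self.status == POTENTIAL and self.mapping_year is not None:
            raise GeodataError(f"potential dataset {self.dataset_id!r} must not have a mapping_year")


@dataclass
class ForestPolygon:
    """One primary-forest polygon with its stratum attributes."""

    polygon_id: str
    dataset_id: str
    geometry: BaseGeometry
    country: str
    bioregion: str
    in_eu: bool

    def __post_init__(self) -> None:
        if self.geometry is None or self.geometry.is_empty:
            raise GeodataError(f"polygon {self.polygon_id!r} has empty geometry")
        if not self.geometry.is_valid:
            raise GeodataError(f"polygon {self.polygon_id!r} has invalid geometry")
        for attr in ("country", "bioregion"):
            if not getattr(self, attr):
                raise GeodataError(f"polygon {self.polygon_id!r} missing {attr}")


def rasterize_polygon(polygon: ForestPolygon | BaseGeometry, grid: Grid) -> tuple[np.ndarray, np.ndarray]:
    """Resolve a polygon to the set of grid cells whose centers it contains.

    Containment follows the lower-left half-open rule: a center lying exactly
    on the polygon boundary counts as inside when it sits on the polygon's
    left (west) or bottom (south) edge and outside on the right/top edge, so
    edge-sharing polygons partition boundary centers without double counting.

    Returns
    -------
    (rows, cols)
        Row/column index arrays (possibly empty) in row-major order.
    """
    geom = polygon.geometry if isinstance(polygon, ForestPolygon) else polygon
    if geom.is_empty:
        return np.empty(0, dtype=np.intp), np.empty(0, dtype=np.intp)
    if not geom.is_valid:
        raise GeodataError("cannot rasterize invalid geometry")

    x0, y0 = grid.origin
    s = grid.cell_size
    minx, miny, maxx, maxy = geom.bounds
    # Candidate cell window from the bounding box, clipped to the grid.
    c0 = max(int(np.floor((minx - x0) / s - 0.5)), 0)
    c1 = min(int(np.ceil((maxx - x0) / s - 0.5)), grid.ncols - 1)
    r0 = max(int(np.floor((y0 - maxy) / s - 0.5)), 0)
    r1 = min(int(np.ceil((y0 - miny) / s - 0.5)), grid.nrows - 1)
    if c1 < c0 or r1 < r0:
        return np.empty(0, dtype=np.intp), np.empty(0, dtype=np.intp)

    rows = np.arange(r0, r1 + 1, dtype=np.intp)
    cols = np.arange(c0, c1 + 1, dtype=np.intp)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    x, y = grid.cell_center(rr.ravel(), cc.ravel())
    # Nudge toward the upper-right so boundary centers obey the half-open rule.
    eps = s * 1e-9
    shapely.prepare(geom)
    inside = shapely.contains_xy(geom, x + eps, y + eps)
    return rr.ravel()[inside], cc.ravel()[inside]


# ---------------------------------------------------------------------------
# Raster I/O (GeoTIFF via tifffile)
# ---------------------------------------------------------------------------

def _write_band(path: Path, data: np.ndarray, grid: Grid, meta: dict) -> None:
    import tifffile

    x0, y0 = grid.origin
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (float(grid.cell_size), float(grid.cell_size), 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, float(x0), float(y0), 0.0)),
    ]
    desc = json.dumps({"crs_tag": grid.crs_tag, **meta})
    tifffile.imwrite(str(path), data, extratags=extratags, description=desc)


def _read_band(path: Path) -> tuple[np.ndarray, Grid, dict]:
    import tifffile

    with tifffile.TiffFile(str(path)) as tf:
        page = tf.pages[0]
        data = page.asarray()
        try:
            sx, sy, _ = page.tags[_TAG_PIXEL_SCALE].value
            tie = page.tags[_TAG_TIEPOINT].value
        except KeyError as exc:
            raise GeodataError(f"{path}: missing GeoTIFF georeferencing tags") from exc
        meta = {}
        if page.description:
            try:
                meta = json.loads(page.description)
            except json.JSONDecodeError:
                meta = {}
    if not np.isclose(sx, sy):
        raise GeodataError(f"{path}: non-square cells ({sx} x {sy}) are not supported")
    grid = Grid(
        nrows=data.shape[0],
        ncols=data.shape[1],
        cell_size=float(sx),
        origin=(float(tie[3]), float(tie[4])),
        crs_tag=str(meta.get("crs_tag", "unknown")),
    )
    return data, grid, meta


def write_layers(layers: DisturbanceLayers, year_path, severity_path, forest_path) -> None:
    """Write the three layers as single-band GeoTIFFs (int16/float32/uint8)."""
    meta = {
        "year_min": layers.year_min,
        "year_max": layers.year_max,
        "severity_year_max": layers.severity_year_max,
    }
    _write_band(Path(year_path), layers.year.astype(np.int16), layers.grid, meta)
    _write_band(Path(severity_path), layers.severity.astype(np.float32), layers.grid, meta)
    _write_band(Path(forest_path), layers.forest.astype(np.uint8), layers.grid, meta)


def read_layers(
    year_path,
    severity_path,
    forest_path,
    year_min: int | None = None,
    year_max: int | None = None,
    severity_year_max: int | None = None,
) -> DisturbanceLayers:
    """Read and validate the three co-registered GeoTIFF layers.

    The analysis window defaults to the values stored at write time (falling
    back to 1986-2020 / 2016).  Shape or georeferencing mismatches between
    the three files raise :class:`GeodataError`.
    """
    year, grid, meta = _read_band(Path(year_path))
    sev, grid_s, _ = _read_band(Path(severity_path))
    forest, grid_f, _ = _read_band(Path(forest_path))
    for other, name in ((grid_s, "severity"), (grid_f, "forest")):
        if (other.shape != grid.shape or not np.isclose(other.cell_size, grid.cell_size)
                or not np.allclose(other.origin, grid.origin)):
            raise GeodataError(f"{name} raster is not co-registered with the year raster")
    return DisturbanceLayers(
        grid=grid,
        year=year,
        severity=sev,
        forest=forest.astype(bool),
        year_min=int(year_min if year_min is not None else meta.get("year_min", 1986)),
        year_max=int(year_max if year_max is not None else meta.get("year_max", 2020)),
        severity_year_max=int(
            severity_year_max if severity_year_max is not None else meta.get("severity_year_max", 2016)
        ),
    )


# ---------------------------------------------------------------------------
# Vector / table I/O (GeoJSON + CSV)
# ---------------------------------------------------------------------------

def write_polygons(polygons: Sequence[ForestPolygon], path) -> None:
    """Write a polygon layer as a GeoJSON FeatureCollection."""
    features = [
        {
            "type": "Feature",
            "geometry": geom_mapping(p.geometry),
            "properties": {
                "polygon_id": p.polygon_id,
                "dataset_id": p.dataset_id,
                "country": p.country,
                "bioregion": p.bioregion,
                "in_eu": bool(p.in_eu),
            },
        }
        for p in polygons
    ]
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": features}))


def read_polygons(path) -> list[ForestPolygon]:
    """Read a GeoJSON polygon layer with the required attribute columns."""
    obj = json.loads(Path(path).read_text())
    polys = []
    for feat in obj.get("features", []):
        props = feat.get("properties", {})
        missing = [k for k in ("polygon_id", "dataset_id", "country", "bioregion", "in_eu") if k not in props]
        if missing:
            raise GeodataError(f"feature missing required properties: {missing}")
        polys.append(
            ForestPolygon(
                polygon_id=str(props["polygon_id"]),
                dataset_id=str(props["dataset_id"]),
                geometry=geom_shape(feat["geometry"]),
                country=str(props["country"]),
                bioregion=str(props["bioregion"]),
                in_eu=bool(props["in_eu"]),
            )
        )
    return polys


def write_datasets(datasets: Sequence[PolygonDataset], path) -> None:
    pd.DataFrame(
        {
            "dataset_id": [d.dataset_id for d in datasets],
            "status": [d.status for d in datasets],
            "mapping_year": [d.mapping_year if d.mapping_year is not None else "" for d in datasets],
        }
    ).to_csv(path, index=False)


def read_datasets(path) -> list[PolygonDataset]:
    df = pd.read_csv(path, dtype={"dataset_id": str, "status": str})
    out = []
    for _, row in df.iterrows():
        my = row.get("mapping_year")
        mapping_year = None if pd.isna(my) or my == "" else int(my)
        out.append(PolygonDataset(str(row["dataset_id"]), str(row["status"]), mapping_year))
    return out


def read_reported_areas(path) -> pd.DataFrame:
    """Read a country-level reported primary-forest area table.

    Expected columns: ``country``, ``reported_area_ha``, optional ``source``.
    """
    df = pd.read_csv(path, dtype={"country": str})
    if "country" not in df or "reported_area_ha" not in df:
        raise GeodataError("reported-area table requires columns 'country' and 'reported_area_ha'")
    if (df["reported_area_ha"] < 0).any():
        raise GeodataError("reported areas must be non-negative")
    return df
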