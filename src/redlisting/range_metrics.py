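"""IUCN criterion B range metrics: EOO, AOO, elevation range, countries.

EOO (extent of occurrence) is the planar area of the minimum convex
polygon around all known or predicted sites, in km².  AOO (area of
occupancy) is 4 km² times the number of distinct occupied cells of a
fixed 2 km × 2 km grid, the resolution IUCN mandates.  Both accept
either occurrence records or a binary presence raster; raster presence
cells contribute their centres as sites for EOO and their full footprint
(any-overlap rule) for AOO.

Degenerate hulls (one or two sites, collinear sites) have zero polygon
area; because IUCN practice requires EOO ≥ AOO, the reported EOO is
floored at the AOO of the same sites.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from shapely.geometry import MultiPoint, Point, shape

from .errors import DataError
from .occurrences import OccurrenceSet, project_to_metric
from .raster import RasterLayer

#: Edge length of the IUCN AOO grid, metres.
AOO_CELL_M = 2000.0


def _metric_sites(records_or_raster) -> np.ndarray:
    """Metric (x, y) site coordinates from records or a presence raster."""
    if isinstance(records_or_raster, OccurrenceSet):
        return project_to_metric(records_or_raster).coords
    if isinstance(records_or_raster, RasterLayer):
        layer = records_or_raster
        r, c = np.nonzero(layer.mask & (layer.values > 0))
        if len(r) == 0:
            raise DataError("no presences")
        x, y = layer.cell_center(r, c)
        return np.column_stack([x, y])
    raise DataError(f"unsupported range input type {type(records_or_raster).__name__}")


def _aoo_cells_from_points(pts: np.ndarray) -> set[tuple[int, int]]:
    ix = np.floor(pts[:, 0] / AOO_CELL_M).astype(int)
    iy = np.floor(pts[:, 1] / AOO_CELL_M).astype(int)
    return set(zip(ix.tolist(), iy.tolist()))


def _aoo_cells_from_raster(layer: RasterLayer) -> set[tuple[int, int]]:
    """2-km grid cells overlapped by any presence cell (any-overlap rule)."""
    r, c = np.nonzero(layer.mask & (layer.values > 0))
    if len(r) == 0:
        raise DataError("no presences")
    s = layer.cell_size
    x0, ytop = layer.origin
    eps = 1e-9 * AOO_CELL_M
    cells: set[tuple[int, int]] = set()
    xmin = x0 + c * s
    ymax = ytop - r * s
    i0 = np.floor(xmin / AOO_CELL_M).astype(int)
    i1 = np.floor((xmin + s - eps) / AOO_CELL_M).astype(int)
    j0 = np.floor((ymax - s) / AOO_CELL_M).astype(int)
    j1 = np.floor((ymax - eps) / AOO_CELL_M).astype(int)
    for a0, a1, b0, b1 in zip(i0, i1, j0, j1):
        for i in range(a0, a1 + 1):
            for j in range(b0, b1 + 1):
                cells.add((i, j))
    return cells


def aoo(records_or_raster) -> float:
    """Area of occupancy in km² on the fixed 2 × 2 km grid.

    The grid is anchored at the metric origin (0, 0); records are binned
    by which 2-km cell contains them, presence rasters by which 2-km
    cells their presence cells overlap.  Always a multiple of 4 km².
    """
    if isinstance(records_or_raster, RasterLayer):
        cells = _aoo_cells_from_raster(records_or_raster)
    else:
        cells = _aoo_cells_from_points(_metric_sites(records_or_raster))
    return 4.0 * len(cells)


def eoo(records_or_raster) -> float:
    """Extent of occurrence in km²: convex-hull area, floored at AOO."""
    sites = _metric_sites(records_or_raster)
    hull_km2 = MultiPoint(sites).convex_hull.area / 1e6
    floor = aoo(records_or_raster)
    return max(hull_km2, floor)


@dataclass(frozen=True)
class RangeValue:
    """Paired EOO and AOO for one range estimate, in km²."""

    eoo_km2: float
    aoo_km2: float


def range_value(records_or_raster) -> RangeValue:
    """EOO and AOO of the same input as a :class:`RangeValue`."""
    return RangeValue(eoo(records_or_raster), aoo(records_or_raster))


def elevation_range(records: OccurrenceSet, dem: RasterLayer) -> tuple[float, float]:
    """Min and max DEM values at the record cells, in DEM units (metres).

    Every record must fall on a DEM data cell; run
    :func:`redlisting.qc.move_to_valid` first if some do not.
    """
    vals = dem.sample(records.coords)
    bad = np.nonzero(~np.isfinite(vals))[0]
    if len(bad):
        raise DataError(f"records on NoData cells at indices {bad.tolist()}; run move_to_valid first")
    return float(np.min(vals)), float(np.max(vals))


def read_boundaries(path) -> list[tuple[str, object]]:
    """Read named boundary polygons from GeoJSON.

    Each feature must carry a ``name`` property and a Polygon or
    MultiPolygon geometry.
    """
    with open(Path(path)) as fh:
        gj = json.load(fh)
    feats = gj["features"] if gj.get("type") == "FeatureCollection" else [gj]
    out = []
    for f in feats:
        name = (f.get("properties") or {}).get("name")
        if name is None:
            raise DataError(f"{path}: boundary feature without a 'name' property")
        out.append((str(name), shape(f["geometry"])))
    return out


def countries_of(range_input, boundaries) -> list[str]:
    """Sorted unique names of boundary polygons containing ≥1 site.

    ``boundaries`` is a list of (name, shapely polygon) pairs in the
    same coordinate system as the input; points on a polygon edge count
    as inside.  Records are used as-is (no projection) so user-supplied
    geographic boundaries pair with geographic records.
    """
    if isinstance(range_input, OccurrenceSet):
        pts = range_input.coords
    else:
        pts = _metric_sites(range_input)
    names = set()
    for name, poly in boundaries:
        if any(poly.covers(Point(x, y)) for x, y in pts):
            names.add(name)
    return sorted(names)
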