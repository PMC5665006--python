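"""Gridded raster layers and stacks with GeoTIFF / ESRI ASCII I/O.

Rasters are north-up regular grids.  Row 0 is the top row; cell (r, c)
has its centre at ``(origin_x + (c + 0.5) * cell_size,
origin_y - (r + 0.5) * cell_size)`` where ``origin`` is the top-left
corner of the grid.  NoData cells are stored as NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import tifffile

from .errors import DataError

_NODATA_OUT = -9999.0

# GeoTIFF tag codes: pixel scale, tiepoint, GDAL nodata
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


@dataclass
class RasterLayer:
    """A single-band raster.

    Attributes
    ----------
    values : ndarray (rows, cols), float
        Cell values; NaN marks NoData.
    cell_size : float
        Cell edge length in map units (metres for metric rasters).
    origin : (float, float)
        (x of the left edge, y of the TOP edge).
    crs : {"geographic", "metric"}
    name : str
        Layer name (used in stacks and file output).
    categorical : bool
        True for class-coded layers (e.g. land cover).
    """

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    crs: str = "metric"
    name: str = "layer"
    categorical: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or min(self.values.shape) < 1:
            raise DataError("raster grid must be 2-D with at least one cell")
        if not self.cell_size > 0:
            raise DataError("cell size must be positive")
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def mask(self) -> np.ndarray:
        """Boolean grid, True where the cell holds data."""
        return np.isfinite(self.values)

    def cell_of(self, x, y):
        """Row/col of the cell containing each point (may fall off-grid)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        c = np.floor((x - self.origin[0]) / self.cell_size).astype(int)
        r = np.floor((self.origin[1] - y) / self.cell_size).astype(int)
        return r, c

    def in_bounds(self, r, c):
        rows, cols = self.shape
        return (r >= 0) & (r < rows) & (c >= 0) & (c < cols)

    def cell_center(self, r, c):
        x = self.origin[0] + (np.asarray(c) + 0.5) * self.cell_size
        y = self.origin[1] - (np.asarray(r) + 0.5) * self.cell_size
        return x, y

    def data_cell_centers(self) -> np.ndarray:
        """(n, 2) array of centres of all data cells, row-major order."""
        r, c = np.nonzero(self.mask)
        x, y = self.cell_center(r, c)
        return np.column_stack([x, y])

    def sample(self, coords: np.ndarray) -> np.ndarray:
        """Value at the cell containing each (x, y); NaN off-grid or NoData."""
        r, c = self.cell_of(coords[:, 0], coords[:, 1])
        ok = self.in_bounds(r, c)
        out = np.full(len(coords), np.nan)
        out[ok] = self.values[r[ok], c[ok]]
        return out

    def copy_with(self, values: np.ndarray, **kw) -> "RasterLayer":
        return replace(self, values=values, **kw)


@dataclass
class RasterStack:
    """An ordered collection of congruent :class:`RasterLayer` bands."""

    layers: list[RasterLayer] = field(default_factory=list)

    def __post_init__(self):
        if not self.layers:
            raise DataError("empty raster stack")
        ref = self.layers[0]
        for lyr in self.layers[1:]:
            if lyr.shape != ref.shape or lyr.cell_size != ref.cell_size or lyr.origin != ref.origin:
                raise DataError("stack layers are not congruent")

    def __len__(self) -> int:
        return len(self.layers)

    def __getitem__(self, i) -> RasterLayer:
        return self.layers[i]

    def __iter__(self):
        return iter(self.layers)

    @property
    def grid(self) -> RasterLayer:
        return self.layers[0]

    @property
    def names(self) -> list[str]:
        return [l.name for l in self.layers]

    def quantitative(self) -> "RasterStack":
        q = [l for l in self.layers if not l.categorical]
        if not q:
            raise DataError("stack has no quantitative layers")
        return RasterStack(q)

    def common_mask(self) -> np.ndarray:
        m = self.layers[0].mask
        for lyr in self.layers[1:]:
            m = m & lyr.mask
        return m

    def sample(self, coords: np.ndarray) -> np.ndarray:
        """(n_records, n_layers) table of layer values at record cells."""
        return np.column_stack([l.sample(coords) for l in self.layers])


# ---------------------------------------------------------------------------
# ESRI ASCII grid
# ---------------------------------------------------------------------------

def write_ascii_grid(layer: RasterLayer, path) -> None:
    """Write a layer as an ESRI ASCII grid (.asc)."""
    rows, cols = layer.shape
    x0, ytop = layer.origin
    yll = ytop - rows * layer.cell_size
    vals = np.where(layer.mask, layer.values, _NODATA_OUT)
    with open(path, "w") as fh:
        fh.write(f"ncols {cols}\n")
        fh.write(f"nrows {rows}\n")
        fh.write(f"xllcorner {x0!r}\n")
        fh.write(f"yllcorner {yll!r}\n")
        fh.write(f"cellsize {layer.cell_size!r}\n")
        fh.write(f"NODATA_value {_NODATA_OUT!r}\n")
        for row in vals:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_ascii_grid(path, name: str = "") -> RasterLayer:
    """Read an ESRI ASCII grid (.asc); NODATA_value cells become NaN."""
    header: dict[str, float] = {}
    data_lines: list[str] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value") and len(parts) == 2:
                header[key] = float(parts[1])
            else:
                data_lines.append(line)
    for req in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if req not in header:
            raise DataError(f"{path}: missing ASCII-grid header field {req}")
    vals = np.loadtxt(data_lines, dtype=float, ndmin=2)
    rows, cols = int(header["nrows"]), int(header["ncols"])
    if vals.shape != (rows, cols):
        vals = vals.reshape(rows, cols)
    nodata = header.get("nodata_value")
    if nodata is not None:
        vals = np.where(vals == nodata, np.nan, vals)
    cell = header["cellsize"]
    origin = (header["xllcorner"], header["yllcorner"] + rows * cell)
    return RasterLayer(vals, cell, origin, name=name or str(path))


# ---------------------------------------------------------------------------
# GeoTIFF (via tifffile; georeferencing written as raw GeoTIFF tags)
# ---------------------------------------------------------------------------

def _geo_extratags(layer: RasterLayer):
    sx = sy = layer.cell_size
    x0, ytop = layer.origin
    return [
        (_TAG_PIXEL_SCALE, "d", 3, (sx, sy, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, x0, ytop, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, str(_NODATA_OUT)),
    ]


def write_geotiff(source: RasterLayer | RasterStack, path) -> None:
    """Write a layer (single band) or stack (one page per band) as GeoTIFF."""
    layers = source.layers if isinstance(source, RasterStack) else [source]
    with tifffile.TiffWriter(str(path)) as tif:
        for lyr in layers:
            vals = np.where(lyr.mask, lyr.values, _NODATA_OUT).astype(np.float64)
            tif.write(
                vals,
                extratags=_geo_extratags(lyr),
                description=lyr.name,
                metadata=None,
            )


def read_geotiff(path) -> RasterStack:
    """Read a single- or multi-band GeoTIFF written by :func:`write_geotiff`.

    Also accepts GeoTIFFs from other producers as long as they carry the
    ModelPixelScale and ModelTiepoint tags with square pixels.
    """
    layers = []
    with tifffile.TiffFile(str(path)) as tif:
        for i, page in enumerate(tif.pages):
            vals = page.asarray().astype(float)
            if vals.ndim != 2:
                raise DataError(f"{path}: band {i} is not a 2-D grid")
            tags = {t.code: t.value for t in page.tags.values()}
            if _TAG_PIXEL_SCALE not in tags or _TAG_TIEPOINT not in tags:
                raise DataError(f"{path}: missing GeoTIFF georeferencing tags")
            sx, sy = tags[_TAG_PIXEL_SCALE][0], tags[_TAG_PIXEL_SCALE][1]
            if abs(sx - sy) > 1e-9 * max(sx, sy):
                raise DataError(f"{path}: non-square pixels unsupported")
            tie = tags[_TAG_TIEPOINT]
            # tiepoint maps raster (i,j) to model (x,y); we require the (0,0) corner
            x0 = tie[3] - tie[0] * sx
            ytop = tie[4] + tie[1] * sy
            nodata = tags.get(_TAG_GDAL_NODATA)
            if nodata is not None:
                vals = np.where(vals == float(nodata), np.nan, vals)
            name = page.description or f"band{i + 1}"
            layers.append(RasterLayer(vals, float(sx), (x0, ytop), name=name))
    if not layers:
        raise DataError(f"{path}: no raster bands found")
    return RasterStack(layers)
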