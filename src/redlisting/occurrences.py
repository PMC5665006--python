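"""Occurrence records and projection to a metric, equal-area plane.

Occurrence records are (x, y) coordinate pairs, either geographic
(longitude/latitude in decimal degrees) or already planar in metres
(e.g. UTM).  Because the range metrics downstream (EOO, AOO) are areas,
geographic records are projected with a Lambert azimuthal equal-area
projection centred on the record centroid: area distortion is the error
that matters, and the azimuthal equal-area projection is exact in area
everywhere on the sphere.

The projection uses the spherical formulas with the authalic Earth
radius, so planar areas equal the corresponding areas on the authalic
sphere.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DataError

#: Authalic Earth radius in metres (sphere with the same surface area as
#: the WGS84 ellipsoid).
EARTH_RADIUS_M = 6_371_007.181


@dataclass(frozen=True)
class LambertAzimuthalEqualArea:
    """Spherical Lambert azimuthal equal-area projection.

    Parameters
    ----------
    lon0, lat0 : float
        Projection centre in decimal degrees.  The centre maps to (0, 0).
    radius : float
        Sphere radius in metres.
    """

    lon0: float
    lat0: float
    radius: float = EARTH_RADIUS_M

    def forward(self, lon, lat):
        """Project lon/lat (degrees) to planar x/y (metres)."""
        lam = np.radians(np.asarray(lon, dtype=float)) - np.radians(self.lon0)
        phi = np.radians(np.asarray(lat, dtype=float))
        phi0 = np.radians(self.lat0)
        denom = 1.0 + np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(lam)
        # denom -> 0 only at the antipode of the centre; records never get there
        k = np.sqrt(2.0 / denom)
        x = self.radius * k * np.cos(phi) * np.sin(lam)
        y = self.radius * k * (np.cos(phi0) * np.sin(phi) - np.sin(phi0) * np.cos(phi) * np.cos(lam))
        return x, y

    def inverse(self, x, y):
        """Inverse projection: planar x/y (metres) back to lon/lat (degrees)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        rho = np.hypot(x, y)
        phi0 = np.radians(self.lat0)
        with np.errstate(invalid="ignore"):
            c = 2.0 * np.arcsin(np.clip(rho / (2.0 * self.radius), -1.0, 1.0))
        sin_c, cos_c = np.sin(c), np.cos(c)
        # guard rho == 0 (the projection centre itself)
        safe_rho = np.where(rho == 0.0, 1.0, rho)
        phi = np.arcsin(cos_c * np.sin(phi0) + y * sin_c * np.cos(phi0) / safe_rho)
        lam = np.arctan2(x * sin_c, safe_rho * np.cos(phi0) * cos_c - y * np.sin(phi0) * sin_c)
        phi = np.where(rho == 0.0, phi0, phi)
        lam = np.where(rho == 0.0, 0.0, lam)
        return np.degrees(lam) + self.lon0, np.degrees(phi)


def detect_crs(coords: np.ndarray) -> str:
    """Guess whether coordinates are geographic or metric.

    Coordinates all within [-180, 180] x [-90, 90] are treated as
    geographic; anything else as metric.  Override with an explicit tag
    when building the :class:`OccurrenceSet`.
    """
    x, y = coords[:, 0], coords[:, 1]
    if np.all(np.abs(x) <= 180.0) and np.all(np.abs(y) <= 90.0):
        return "geographic"
    return "metric"


@dataclass
class OccurrenceSet:
    """An ordered set of occurrence records.

    Attributes
    ----------
    coords : ndarray of shape (n, 2)
        x (longitude or easting) then y (latitude or northing).
    crs : {"geographic", "metric"}
        Coordinate-system tag.  Autodetected when not supplied.
    projection : LambertAzimuthalEqualArea, optional
        Set on metric sets produced by :func:`project_to_metric`, so the
        planar frame can be inverted back to lon/lat (KML export).
    """

    coords: np.ndarray
    crs: str = ""
    projection: LambertAzimuthalEqualArea | None = field(default=None, compare=False)

    def __post_init__(self):
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        if self.coords.size == 0:
            raise DataError("no records")
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise DataError("records must be an (n, 2) array of x,y pairs")
        if np.any(~np.isfinite(self.coords)):
            raise DataError("records contain NaN/Inf coordinates")
        if not self.crs:
            self.crs = detect_crs(self.coords)
        if self.crs not in ("geographic", "metric"):
            raise DataError(f"unknown crs tag {self.crs!r}")
        if self.crs == "geographic":
            x, y = self.coords[:, 0], self.coords[:, 1]
            if np.any(np.abs(x) > 180.0) or np.any(np.abs(y) > 90.0):
                raise DataError("geographic coordinates outside [-180,180] x [-90,90]")

    def __len__(self) -> int:
        return len(self.coords)

    def subset(self, indices) -> "OccurrenceSet":
        return OccurrenceSet(self.coords[np.asarray(indices)], self.crs, self.projection)


def project_to_metric(records: OccurrenceSet) -> OccurrenceSet:
    """Project geographic records to a metric equal-area plane.

    Metric inputs are returned unchanged.  Geographic inputs are projected
    with a Lambert azimuthal equal-area projection centred on the records'
    centroid (mean longitude/latitude), so the centroid of a single record
    maps to (0, 0).
    """
    if len(records) == 0:
        raise DataError("no records")
    if records.crs == "metric":
        return records
    lon0 = float(np.mean(records.coords[:, 0]))
    lat0 = float(np.mean(records.coords[:, 1]))
    proj = LambertAzimuthalEqualArea(lon0, lat0)
    x, y = proj.forward(records.coords[:, 0], records.coords[:, 1])
    return OccurrenceSet(np.column_stack([x, y]), "metric", projection=proj)


def read_occurrences(path) -> OccurrenceSet | dict[str, OccurrenceSet]:
    """Read occurrence records from CSV.

    Two numeric columns (x/longitude, y/latitude) give a single
    :class:`OccurrenceSet`; three columns (species, x, y) give a dict of
    species name -> OccurrenceSet.  An optional header row and blank
    lines are skipped.  Non-numeric coordinates raise :class:`DataError`
    with the offending line number.
    """
    path = Path(path)
    rows: list[list[str]] = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or all(not c.strip() for c in row):
                continue
            rows.append([lineno] + [c.strip() for c in row])
    if not rows:
        raise DataError(f"{path}: no records")

    def _is_number(s: str) -> bool:
        try:
            float(s)
            return True
        except ValueError:
            return False

    ncol = len(rows[0]) - 1
    if ncol not in (2, 3):
        raise DataError(f"{path}: expected 2 or 3 columns, found {ncol}")
    # header row: coordinate columns not numeric
    first = rows[0]
    if not (_is_number(first[-2]) and _is_number(first[-1])):
        rows = rows[1:]
        if not rows:
            raise DataError(f"{path}: no records")

    if ncol == 2:
        coords = []
        for lineno, xs, ys in rows:
            if not (_is_number(xs) and _is_number(ys)):
                raise DataError(f"{path}: non-numeric coordinate on line {lineno}")
            coords.append((float(xs), float(ys)))
        return OccurrenceSet(np.array(coords))

    by_species: dict[str, list[tuple[float, float]]] = {}
    for lineno, sp, xs, ys in rows:
        if not (_is_number(xs) and _is_number(ys)):
            raise DataError(f"{path}: non-numeric coordinate on line {lineno}")
        by_species.setdefault(sp, []).append((float(xs), float(ys)))
    return {sp: OccurrenceSet(np.array(c)) for sp, c in by_species.items()}


def write_occurrences(records: OccurrenceSet, path, header: bool = True) -> None:
    """Write records as a two-column CSV (x, y) with full float precision."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        if header:
            w.writerow(["x", "y"])
        for x, y in records.coords:
            w.writerow([repr(float(x)), repr(float(y))])
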