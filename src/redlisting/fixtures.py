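"""Synthetic landscapes, virtual species, and category tables.

Everything the toolkit consumes can be simulated here, offline:

* :func:`gen_landscape` — smoothed Gaussian-random-field climate and
  elevation layers plus a categorical land-cover layer, optionally
  masked to an island (NoData "sea" cells);
* :func:`gen_virtual_species` — a species whose true suitability is a
  logistic response to the standardized layers, so the true range is
  known exactly and recovery by the modelling pipeline can be scored;
* :func:`gen_occurrences` — sampling records from the true range,
  optionally spatially clustered (to exercise thinning) or displaced
  off valid cells (to exercise snapping and outlier detection);
* :func:`gen_category_table` — Red List category trajectories evolved
  by a Markov transition matrix across assessment dates;
* :func:`island_spider` — the default worked example: a 100 × 100 km
  island with two climate layers, elevation and 4-class land cover, and
  10 records of a single-island endemic, one of which sits in the sea.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import expit

from .errors import DataError, UsageError
from .occurrences import OccurrenceSet
from .raster import RasterLayer, RasterStack

_CODES = ["LC", "NT", "VU", "EN", "CR", "EX"]


def _smooth_field(rng: np.random.Generator, rows: int, cols: int, scale: float) -> np.ndarray:
    """Unit-variance Gaussian random field with correlation length ~scale."""
    field = rng.standard_normal((rows, cols))
    if scale > 0:
        field = ndimage.gaussian_filter(field, sigma=scale, mode="reflect")
    sd = field.std()
    return (field - field.mean()) / (sd if sd > 0 else 1.0)


def gen_landscape(
    rows: int = 100,
    cols: int = 100,
    cell_size: float = 1000.0,
    n_quant_layers: int = 3,
    n_classes: int = 4,
    spatial_scale: float = 8.0,
    island: bool = True,
    seed=None,
) -> RasterStack:
    """Generate a synthetic landscape raster stack.

    Quantitative layers are smoothed Gaussian random fields (the first
    two named like climate variables, the last "elevation", rescaled to
    0–1800 m); one categorical land-cover layer is produced by
    quantile-thresholding a further field into ``n_classes`` classes.
    With ``island=True`` cells outside a smoothed blob around the grid
    centre are NoData on every layer, emulating the sea around an
    island.
    """
    if rows < 8 or cols < 8:
        raise UsageError("landscape must be at least 8 x 8")
    rng = np.random.default_rng(seed)
    origin = (0.0, rows * cell_size)

    if island:
        blob = _smooth_field(rng, rows, cols, max(spatial_scale, 4.0))
        yy, xx = np.mgrid[0:rows, 0:cols]
        cy, cx = (rows - 1) / 2, (cols - 1) / 2
        radial = 1.0 - np.hypot((yy - cy) / (rows / 2), (xx - cx) / (cols / 2))
        mask = (radial + 0.35 * blob) > 0.25
        # keep only the largest connected landmass
        labels, nlab = ndimage.label(mask)
        if nlab > 1:
            sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, nlab + 1))
            mask = labels == (1 + int(np.argmax(sizes)))
    else:
        mask = np.ones((rows, cols), dtype=bool)

    names = ["temperature", "precipitation", "elevation"]
    layers = []
    for i in range(n_quant_layers):
        field = _smooth_field(rng, rows, cols, spatial_scale)
        name = names[i] if i < len(names) else f"env{i + 1}"
        if name == "elevation":
            lo, hi = field.min(), field.max()
            field = 1800.0 * (field - lo) / (hi - lo if hi > lo else 1.0)
        vals = np.where(mask, field, np.nan)
        layers.append(RasterLayer(vals, cell_size, origin, name=name))

    cover_field = _smooth_field(rng, rows, cols, spatial_scale)
    edges = np.quantile(cover_field[mask], np.linspace(0, 1, n_classes + 1)[1:-1])
    classes = np.digitize(cover_field, edges) + 1.0
    layers.append(
        RasterLayer(
            np.where(mask, classes, np.nan), cell_size, origin, name="landcover", categorical=True
        )
    )
    return RasterStack(layers)


@dataclass
class VirtualSpecies:
    """A simulated species with known true suitability and range."""

    suitability: RasterLayer  # true suitability in [0, 1]
    presence: RasterLayer  # binary: suitability >= cutoff
    coefficients: np.ndarray
    cutoff: float


def gen_virtual_species(
    landscape: RasterStack,
    coefficients,
    cutoff: float = 0.5,
    intercept: float = 0.0,
) -> VirtualSpecies:
    """Define a virtual species by a logistic response to the layers.

    Suitability is ``logistic(intercept + sum(coef_i * z_i))`` over the
    standardized quantitative layers; true presence is suitability >=
    ``cutoff``.
    """
    quant = landscape.quantitative()
    coefficients = np.asarray(coefficients, dtype=float)
    if len(coefficients) != len(quant):
        raise UsageError(
            f"need {len(quant)} coefficients (one per quantitative layer), got {len(coefficients)}"
        )
    if np.all(coefficients == 0):
        import warnings

        warnings.warn("all-zero coefficients: suitability is uniform 0.5")
    mask = quant.common_mask()
    lin = np.full(quant.grid.shape, float(intercept))
    for coef, lyr in zip(coefficients, quant):
        v = lyr.values[mask]
        z = (lyr.values - v.mean()) / (v.std() if v.std() > 0 else 1.0)
        lin = lin + coef * z
    suit = np.where(mask, expit(lin), np.nan)
    pres = np.where(mask, (suit >= cutoff).astype(float), np.nan)
    grid = quant.grid
    return VirtualSpecies(
        suitability=grid.copy_with(suit, name="true_suitability"),
        presence=grid.copy_with(pres, name="true_presence"),
        coefficients=coefficients,
        cutoff=cutoff,
    )


def gen_occurrences(
    species: VirtualSpecies,
    n: int = 10,
    bias: str = "none",
    error_rate: float = 0.0,
    seed=None,
) -> OccurrenceSet:
    """Sample occurrence records from a virtual species' true range.

    Records are cell centres of presence cells, drawn uniformly or, with
    ``bias="clustered"``, with probability decaying with distance from a
    random focal presence cell (emulating accessibility-driven sampling
    clumping).  With probability ``error_rate`` a record is displaced to
    a random NoData or non-presence cell, producing the misplaced
    records that snapping and outlier screening exist to catch.
    """
    if n < 1:
        raise UsageError("n must be >= 1")
    if bias not in ("none", "clustered"):
        raise UsageError("bias must be 'none' or 'clustered'")
    rng = np.random.default_rng(seed)
    pres = species.presence
    r, c = np.nonzero(pres.mask & (pres.values > 0))
    if len(r) == 0:
        raise DataError("virtual species has no presence cells")
    replace = False
    if n > len(r):
        import warnings

        warnings.warn(f"n={n} exceeds {len(r)} presence cells; sampling with replacement")
        replace = True
    if bias == "none":
        pick = rng.choice(len(r), size=n, replace=replace)
    else:
        focal = rng.integers(len(r))
        d = np.hypot(r - r[focal], c - c[focal])
        w = np.exp(-d / (0.1 * max(pres.shape)))
        p = w / w.sum()
        pick = rng.choice(len(r), size=n, replace=replace, p=p)
    rr, cc = r[pick], c[pick]
    x, y = pres.cell_center(rr, cc)
    coords = np.column_stack([x, y])
    if error_rate > 0:
        bad_r, bad_c = np.nonzero(~(pres.mask & (pres.values > 0)))
        if len(bad_r):
            for i in range(n):
                if rng.random() < error_rate:
                    j = rng.integers(len(bad_r))
                    bx, by = pres.cell_center(bad_r[j], bad_c[j])
                    coords[i] = (bx, by)
    return OccurrenceSet(coords, pres.crs)


def gen_category_table(
    n_species: int = 20,
    n_dates: int = 2,
    transition: np.ndarray | None = None,
    initial: np.ndarray | None = None,
    seed=None,
) -> pd.DataFrame:
    """Simulate a species × dates table of IUCN categories.

    Initial categories are drawn from ``initial`` (default: mass on the
    lower-risk categories, the usual shape of real assessments) and
    evolved date-to-date by the row-stochastic ``transition`` matrix
    over the ladder LC, NT, VU, EN, CR, EX.  The identity matrix gives
    a "null" table (no changes), used for significance calibration.
    """
    k = len(_CODES)
    if transition is None:
        # mild deterioration: most species stay, some slip one category
        transition = np.eye(k) * 0.85
        for i in range(k - 1):
            transition[i, i + 1] = 0.15
        transition[k - 1, k - 1] = 1.0
    transition = np.asarray(transition, dtype=float)
    if transition.shape != (k, k) or not np.allclose(transition.sum(axis=1), 1.0):
        raise UsageError(f"transition must be {k}x{k} with rows summing to 1")
    if initial is None:
        initial = np.array([0.45, 0.2, 0.15, 0.1, 0.07, 0.03])
    initial = np.asarray(initial, dtype=float)
    if len(initial) != k or not np.isclose(initial.sum(), 1.0):
        raise UsageError("initial distribution must sum to 1 over the 6 categories")
    rng = np.random.default_rng(seed)
    states = np.empty((n_species, n_dates), dtype=int)
    states[:, 0] = rng.choice(k, size=n_species, p=initial)
    cum = np.cumsum(transition, axis=1)
    for t in range(1, n_dates):
        u = rng.random(n_species)
        states[:, t] = (u[:, None] > cum[states[:, t - 1]]).sum(axis=1)
    data = np.array(_CODES, dtype=object)[states]
    return pd.DataFrame(
        data,
        index=[f"sp{i + 1}" for i in range(n_species)],
        columns=[str(2000 + 10 * t) for t in range(n_dates)],
    )


def null_transition() -> np.ndarray:
    """Identity transition matrix: categories never change."""
    return np.eye(len(_CODES))


def recovery_setup(
    seed: int = 0, n_records: int = 50
) -> tuple[RasterStack, VirtualSpecies, OccurrenceSet]:
    """Standard virtual-species recovery experiment.

    A mainland-free 100 × 100 km island landscape and a habitat
    specialist with a strong climate response and a negative baseline
    (intercept −3), giving the restricted range typical of species that
    actually reach red-list assessment (roughly a fifth of the land).
    ``n_records`` error-free records are sampled uniformly from the true
    range — the well-surveyed case the modelling pipeline should be able
    to recover.
    """
    rng = np.random.default_rng(seed)
    land = gen_landscape(seed=rng.integers(2**31))
    species = gen_virtual_species(land, coefficients=[3.0, -2.5, 1.5], cutoff=0.7, intercept=-3.0)
    records = gen_occurrences(species, n=n_records, seed=rng.integers(2**31))
    return land, species, records


def island_spider(seed: int = 42) -> tuple[RasterStack, OccurrenceSet, VirtualSpecies]:
    """The default worked example: an island endemic with 10 records.

    Returns a 100 × 100 landscape (1-km cells; two climate layers,
    elevation, 4-class land cover, sea as NoData), a virtual species
    with a strong response to the climate layers, and 10 occurrence
    records sampled from it — one displaced into the sea, the classic
    georeferencing error the QC tools handle.
    """
    land = gen_landscape(seed=seed)
    species = gen_virtual_species(land, coefficients=[2.5, -2.0, 1.0])
    rng = np.random.default_rng(seed + 1)
    rec = gen_occurrences(species, n=10, seed=rng.integers(2**31))
    # displace the last record into the sea (a NoData cell), if any sea exists
    mask = land.common_mask()
    sea_r, sea_c = np.nonzero(~mask)
    if len(sea_r):
        j = rng.integers(len(sea_r))
        x, y = land.grid.cell_center(sea_r[j], sea_c[j])
        coords = rec.coords.copy()
        coords[-1] = (x, y)
        rec = OccurrenceSet(coords, rec.crs)
    return land, rec, species
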