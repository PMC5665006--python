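"""Occurrence-record quality control.

Three cleaning steps commonly needed before range estimation:

* :func:`move_to_valid` — records falling on NoData cells (e.g. in the
  sea on a terrestrial layer, from georeferencing error) are snapped to
  the centre of the nearest cell with data.
* :func:`detect_outliers` — records whose environmental fingerprint is
  unusual are flagged by their Euclidean distance to the centroid of a
  PCA fitted on the standardized environmental values at the record
  cells.  Geographic distances to the record centroid are reported
  alongside so both spaces can be inspected.
* :func:`thin_records` — spatial thinning: randomized removal of records
  until no pair is closer than a threshold distance, repeated over many
  runs, keeping the run that retains the most records.  Mitigates the
  clumped sampling bias that inflates presence density near accessible
  sites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA

from .errors import DataError, UsageError
from .occurrences import OccurrenceSet
from .raster import RasterLayer, RasterStack


def move_to_valid(records: OccurrenceSet, layer: RasterLayer | RasterStack) -> OccurrenceSet:
    """Snap records on NoData (or off-grid) cells to the nearest data cell.

    Nearness is Euclidean distance from the record to candidate data-cell
    centres.  Records already on data cells are returned unchanged and
    record order is preserved.
    """
    grid = layer.grid if isinstance(layer, RasterStack) else layer
    mask = layer.common_mask() if isinstance(layer, RasterStack) else grid.mask
    if not mask.any():
        raise DataError("layer has no data cells")
    r, c = grid.cell_of(records.coords[:, 0], records.coords[:, 1])
    ok = grid.in_bounds(r, c)
    on_data = np.zeros(len(records), dtype=bool)
    on_data[ok] = mask[r[ok], c[ok]]
    if on_data.all():
        return records
    rr, cc = np.nonzero(mask)
    cx, cy = grid.cell_center(rr, cc)
    centers = np.column_stack([cx, cy])
    out = records.coords.copy()
    for i in np.nonzero(~on_data)[0]:
        d2 = np.sum((centers - records.coords[i]) ** 2, axis=1)
        out[i] = centers[np.argmin(d2)]
    return OccurrenceSet(out, records.crs, records.projection)


@dataclass
class OutlierReport:
    """Per-record outlier diagnostics.

    ``geo_dist`` is the distance to the record centroid in map units;
    ``env_dist`` the distance to the PCA centroid in standardized PC
    space (unitless); ``flagged`` marks records with
    ``env_dist > mean + cutoff_sd * SD``.
    """

    geo_dist: np.ndarray
    env_dist: np.ndarray
    flagged: np.ndarray
    pc_scores: np.ndarray
    cutoff_sd: float

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"geo_dist": self.geo_dist, "env_dist": self.env_dist, "flagged": self.flagged}
        )


def detect_outliers(
    records: OccurrenceSet, layers: RasterStack, cutoff_sd: float = 2.0
) -> OutlierReport:
    """Flag records far from the centroid of environmental (PC) space.

    Environmental values at the record cells are standardized per layer
    (zero mean, unit variance over the records), a full-rank PCA is
    fitted, and each record's Euclidean distance to the PC-space centroid
    is computed.  Records beyond ``mean + cutoff_sd * SD`` of these
    distances are flagged.  Zero-variance layers carry no information
    for this statistic and are dropped with a warning.
    """
    if len(records) < 3:
        raise DataError("need at least 3 records for outlier detection")
    quant = layers.quantitative()
    env = quant.sample(records.coords)
    bad = np.nonzero(~np.isfinite(env).all(axis=1))[0]
    if len(bad):
        raise DataError(
            f"records on NoData cells at indices {bad.tolist()}; run move_to_valid first"
        )
    sd = env.std(axis=0)
    keep = sd > 0
    if not keep.all():
        dropped = [quant.names[i] for i in np.nonzero(~keep)[0]]
        warnings.warn(f"dropping zero-variance layers: {dropped}")
    env = env[:, keep]
    if env.shape[1] == 0:
        # all layers constant over the records: every record is at the centroid
        z = np.zeros((len(records), 1))
    else:
        z = (env - env.mean(axis=0)) / env.std(axis=0)
    if np.allclose(z, 0.0):
        scores = z  # all records environmentally identical: nothing to rotate
    else:
        scores = PCA(n_components=min(z.shape)).fit_transform(z)
    env_dist = np.linalg.norm(scores - scores.mean(axis=0), axis=1)
    centroid = records.coords.mean(axis=0)
    geo_dist = np.linalg.norm(records.coords - centroid, axis=1)
    thr = env_dist.mean() + cutoff_sd * env_dist.std()
    flagged = env_dist > thr
    return OutlierReport(geo_dist, env_dist, flagged, scores, cutoff_sd)


@dataclass
class ThinResult:
    """Outcome of spatial thinning."""

    retained: np.ndarray  # indices into the input records, ascending
    min_distance: float  # achieved minimum pairwise distance (inf if < 2 records)
    threshold: float  # distance threshold applied, map units

    def apply(self, records: OccurrenceSet) -> OccurrenceSet:
        return records.subset(self.retained)


def thin_records(
    records: OccurrenceSet,
    proportion: float = 0.1,
    runs: int = 100,
    seed: int | None = None,
) -> ThinResult:
    """Thin records so no two retained are closer than a distance threshold.

    The threshold is ``proportion`` times the maximum pairwise distance
    of the input.  Each run repeatedly picks a uniformly random member
    of a uniformly random violating pair and deletes it until no pair
    violates; the run retaining the most records wins (ties: first such
    run).  Randomized restarts matter because greedy deletion is not
    optimal for the underlying maximum-independent-set problem.
    """
    if not 0 <= proportion < 1:
        raise UsageError("thinning proportion must be in [0, 1)")
    n = len(records)
    if n == 1:
        return ThinResult(np.array([0]), np.inf, 0.0)
    dmat = squareform(pdist(records.coords))
    threshold = proportion * float(dmat.max())
    if threshold == 0.0:
        return ThinResult(np.arange(n), float(dmat[np.triu_indices(n, 1)].min()), 0.0)
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n, 1)
    violating = dmat[iu] < threshold
    base_pairs = np.column_stack([iu[0][violating], iu[1][violating]])
    best: np.ndarray | None = None
    for _ in range(max(1, runs)):
        alive = np.ones(n, dtype=bool)
        pairs = base_pairs
        while len(pairs):
            i, j = pairs[rng.integers(len(pairs))]
            victim = i if rng.random() < 0.5 else j
            alive[victim] = False
            pairs = pairs[(pairs[:, 0] != victim) & (pairs[:, 1] != victim)]
        if best is None or alive.sum() > best.sum():
            best = alive
    retained = np.nonzero(best)[0]
    if len(retained) > 1:
        sub = dmat[np.ix_(retained, retained)]
        min_d = float(sub[np.triu_indices(len(retained), 1)].min())
    else:
        min_d = np.inf
    return ThinResult(retained, min_d, threshold)
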