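"""Presence-background species distribution modelling with ensembles.

The model family is a maxent-style penalized regression: an
L1-regularized logistic model discriminating presence cells from random
background cells on standardized linear + quadratic covariate features.
Ensembles repeat the fit over random 70/30 presence splits and fresh
background samples; per-run binary maps are combined into

* a consensus map — cells where the AUC-weighted vote exceeds 0.5,
  each run weighted ``max(0, AUC - 0.5)**2``;
* two-sided confidence-limit maps — the lower limit keeps cells
  predicted present in at least 97.5% of runs, the upper limit cells
  present in at least 2.5% of runs,

so EOO/AOO come with lower/consensus/upper variants reflecting model
uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from .errors import DataError, UsageError
from .occurrences import OccurrenceSet
from .raster import RasterLayer, RasterStack
from .range_metrics import RangeValue, range_value

MIN_PRESENCES = 5


def sample_background(
    layers: RasterStack, n: int = 1000, seed=None
) -> OccurrenceSet:
    """Sample background ("pseudo-absence") points from the landscape.

    Draws ``n`` distinct data-cell centres uniformly without
    replacement; if the landscape has fewer than ``n`` data cells, all
    are used with a warning.
    """
    grid = layers.grid
    mask = layers.common_mask()
    r, c = np.nonzero(mask)
    if len(r) == 0:
        raise DataError("layers have no data cells")
    rng = np.random.default_rng(seed)
    if len(r) <= n:
        if len(r) < n:
            import warnings

            warnings.warn(f"only {len(r)} data cells available; using all")
        pick = np.arange(len(r))
    else:
        pick = rng.choice(len(r), size=n, replace=False)
    x, y = grid.cell_center(r[pick], c[pick])
    return OccurrenceSet(np.column_stack([x, y]), grid.crs)


class MaxentLikeModel:
    """L1-penalized logistic presence-background model.

    Covariates are standardized using moments from the training table
    and expanded to linear + quadratic features, the standard
    low-complexity maxent feature set.  ``regularization`` scales the L1
    penalty (larger = sparser, smoother response).
    """

    def __init__(self, regularization: float = 1.0):
        if regularization <= 0:
            raise UsageError("regularization multiplier must be positive")
        self.regularization = regularization
        self._mean: np.ndarray | None = None
        self._sd: np.ndarray | None = None
        self._clf: LogisticRegression | None = None

    def _features(self, env: np.ndarray) -> np.ndarray:
        z = (env - self._mean) / self._sd
        return np.column_stack([z, z**2])

    def fit(self, presence_env: np.ndarray, background_env: np.ndarray) -> "MaxentLikeModel":
        presence_env = np.atleast_2d(np.asarray(presence_env, dtype=float))
        background_env = np.atleast_2d(np.asarray(background_env, dtype=float))
        if len(presence_env) < MIN_PRESENCES:
            raise DataError(f"need at least {MIN_PRESENCES} presences, got {len(presence_env)}")
        table = np.vstack([presence_env, background_env])
        if not np.isfinite(table).all():
            raise DataError("NaN in environmental table; run move_to_valid first")
        self._mean = table.mean(axis=0)
        sd = table.std(axis=0)
        self._sd = np.where(sd > 0, sd, 1.0)
        X = self._features(table)
        y = np.r_[np.ones(len(presence_env)), np.zeros(len(background_env))]
        self._clf = LogisticRegression(
            l1_ratio=1.0,
            C=1.0 / self.regularization,
            solver="liblinear",
            max_iter=1000,
            random_state=0,  # liblinear shuffles internally; pin for reproducibility
        ).fit(X, y)
        return self

    def predict(self, env: np.ndarray) -> np.ndarray:
        """Suitability in [0, 1] for each row of covariates."""
        if self._clf is None:
            raise UsageError("model is not fitted")
        env = np.atleast_2d(np.asarray(env, dtype=float))
        return self._clf.predict_proba(self._features(env))[:, 1]


def fit_maxent_like(
    presence_env: np.ndarray, background_env: np.ndarray, regularization: float = 1.0
) -> MaxentLikeModel:
    """Fit the maxent-style penalized logistic model on value tables."""
    return MaxentLikeModel(regularization).fit(presence_env, background_env)


def auc(scores_presence, scores_background) -> float:
    """Probability a random presence outscores a random background point.

    Mann–Whitney formulation; ties count one half.
    """
    sp = np.asarray(scores_presence, dtype=float)
    sb = np.asarray(scores_background, dtype=float)
    if len(sp) == 0 or len(sb) == 0:
        raise DataError("both score sets must be non-empty")
    y = np.r_[np.ones(len(sp)), np.zeros(len(sb))]
    return float(roc_auc_score(y, np.r_[sp, sb]))


def _best_threshold(scores_presence: np.ndarray, scores_background: np.ndarray) -> float:
    """Threshold maximizing sensitivity + specificity (Youden's J).

    Candidates are the observed scores; presence counts as predicted
    when score >= threshold.  Ties in J resolve to the lowest such
    threshold (the most inclusive map).
    """
    cand = np.unique(np.r_[scores_presence, scores_background])
    sens = np.array([(scores_presence >= t).mean() for t in cand])
    spec = np.array([(scores_background < t).mean() for t in cand])
    return float(cand[np.argmax(sens + spec)])


@dataclass
class SdmRun:
    """One fitted run of the ensemble."""

    model: MaxentLikeModel
    probability: RasterLayer  # suitability in [0,1] on data cells
    threshold: float
    test_auc: float
    binary: RasterLayer  # probability >= threshold

    @property
    def weight(self) -> float:
        return max(0.0, self.test_auc - 0.5) ** 2


def _predict_raster(model: MaxentLikeModel, layers: RasterStack) -> RasterLayer:
    mask = layers.common_mask()
    env = np.column_stack([lyr.values[mask] for lyr in layers])
    grid = np.full(layers.grid.shape, np.nan)
    grid[mask] = model.predict(env)
    return layers.grid.copy_with(grid, name="suitability", categorical=False)


def run_ensemble(
    records: OccurrenceSet,
    layers: RasterStack,
    runs: int = 100,
    test_fraction: float = 0.3,
    background_n: int = 1000,
    regularization: float = 1.0,
    seed=None,
) -> list[SdmRun]:
    """Fit an ensemble of maxent-style runs.

    Each run draws a fresh random presence train/test split (70/30 by
    default) and a fresh background sample, fits the model on training
    data, predicts suitability over the landscape, scores test AUC
    (test presences vs held-out background), and binarizes at the
    training-data threshold maximizing sensitivity + specificity.
    Run-to-run variation comes only from these random draws.
    """
    if not 0 < test_fraction < 1:
        raise UsageError("test_fraction must be in (0, 1)")
    quant = layers.quantitative()
    env_rec = quant.sample(records.coords)
    bad = np.nonzero(~np.isfinite(env_rec).all(axis=1))[0]
    if len(bad):
        raise DataError(f"records on NoData cells at indices {bad.tolist()}; run move_to_valid first")
    n = len(records)
    n_test = max(1, int(round(test_fraction * n)))
    if n - n_test < MIN_PRESENCES:
        raise DataError(
            f"only {n - n_test} training presences after the split; need {MIN_PRESENCES}"
        )
    master = np.random.default_rng(seed)
    out: list[SdmRun] = []
    for run_id in range(runs):
        rng = np.random.default_rng(master.integers(2**31))
        try:
            perm = rng.permutation(n)
            test_idx, train_idx = perm[:n_test], perm[n_test:]
            bg = sample_background(quant, background_n, seed=rng.integers(2**31))
            env_bg = quant.sample(bg.coords)
            n_bg_test = max(1, int(round(test_fraction * len(env_bg))))
            bg_perm = rng.permutation(len(env_bg))
            bg_test, bg_train = bg_perm[:n_bg_test], bg_perm[n_bg_test:]
            model = fit_maxent_like(env_rec[train_idx], env_bg[bg_train], regularization)
            prob = _predict_raster(model, quant)
            train_scores_p = model.predict(env_rec[train_idx])
            train_scores_b = model.predict(env_bg[bg_train])
            thr = _best_threshold(train_scores_p, train_scores_b)
            test_auc = auc(model.predict(env_rec[test_idx]), model.predict(env_bg[bg_test]))
            binary = prob.copy_with(
                np.where(prob.mask, (prob.values >= thr).astype(float), np.nan),
                name="presence",
            )
            out.append(SdmRun(model, prob, thr, test_auc, binary))
        except DataError as e:
            raise DataError(f"run {run_id}: {e}") from e
    return out


@dataclass
class EnsembleResult:
    """Consensus and confidence-limit maps with their range metrics."""

    consensus: RasterLayer
    lower: RasterLayer
    upper: RasterLayer
    weights: np.ndarray
    consensus_range: RangeValue
    lower_range: RangeValue | None
    upper_range: RangeValue | None


def consensus_map(
    runs: list[SdmRun],
    lower_freq: float = 0.975,
    upper_freq: float = 0.025,
) -> EnsembleResult:
    """Combine per-run binary maps into consensus and CL maps.

    Consensus: a cell is present iff the weighted vote
    ``sum(w_r * b_r) / sum(w_r)`` strictly exceeds 0.5, with weights
    ``max(0, AUC_r - 0.5)**2``.  Confidence limits use unweighted run
    frequencies: present in >= 97.5% of runs for the lower limit,
    >= 2.5% for the upper.  EOO/AOO are attached for all three maps
    (None where a map is empty).
    """
    if not runs:
        raise DataError("empty ensemble")
    weights = np.array([r.weight for r in runs])
    if weights.sum() == 0:
        raise DataError("ensemble uninformative: all run AUCs <= 0.5")
    grid = runs[0].binary
    stack = np.stack([np.nan_to_num(r.binary.values, nan=0.0) for r in runs])
    mask = grid.mask
    vote = np.tensordot(weights, stack, axes=(0, 0)) / weights.sum()
    freq = stack.mean(axis=0)
    cons = grid.copy_with(np.where(mask, (vote > 0.5).astype(float), np.nan), name="consensus")
    low = grid.copy_with(np.where(mask, (freq >= lower_freq).astype(float), np.nan), name="lower_cl")
    upp = grid.copy_with(np.where(mask, (freq >= upper_freq).astype(float), np.nan), name="upper_cl")

    def _rv(layer: RasterLayer) -> RangeValue | None:
        try:
            return range_value(layer)
        except DataError:
            return None

    cons_rv = _rv(cons)
    if cons_rv is None:
        raise DataError("consensus map is empty")
    return EnsembleResult(cons, low, upp, weights, cons_rv, _rv(low), _rv(upp))


def map_points(records: OccurrenceSet, layers: RasterStack | RasterLayer):
    """Raster of exactly the cells containing records, with EOO/AOO.

    The baseline range map when records are either too few to model or
    complete enough that no extrapolation is needed.
    """
    grid = layers.grid if isinstance(layers, RasterStack) else layers
    r, c = grid.cell_of(records.coords[:, 0], records.coords[:, 1])
    off = np.nonzero(~grid.in_bounds(r, c))[0]
    if len(off):
        raise DataError(f"records outside the raster extent at indices {off.tolist()}")
    pres = np.zeros(grid.shape)
    pres[r, c] = 1.0
    pres = np.where(grid.mask, pres, np.nan)
    layer = grid.copy_with(pres, name="recorded", categorical=False)
    return layer, range_value(records)
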