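"""Red List Index (RLI) with bootstrap confidence limits.

The RLI tracks the aggregate extinction-risk status of a species group
over repeated IUCN assessments.  Each species' category carries a
weight, 0 for Least Concern up to 5 for Extinct / Extinct in the Wild;
the index for one assessment date is

    RLI = 1 - sum(weights) / (5 * N)

with N the number of assessable (non-Data-Deficient) species, so 1
means all species are Least Concern and 0 the worst case, all extinct.

Uncertainty is assessed by bootstrapping species: whole species rows
are resampled with replacement to the original N, preserving the
pairing of categories across dates, and the 2.5/97.5 percentiles of the
replicate indices give the confidence limits.  A change between two
dates is called significant when more than 95% of replicate changes
share the sign of the observed change.

Data Deficient species are excluded from both the weight sum and N by
default, following standard RLI practice; ``dd_weight`` lets callers
pin DD to a fixed weight instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError, UsageError

#: Category -> weight ladder. EW and EX share the top score.
CATEGORY_WEIGHTS: dict[str, int] = {
    "LC": 0,
    "NT": 1,
    "VU": 2,
    "EN": 3,
    "CR": 4,
    "EW": 5,
    "EX": 5,
}

VALID_CODES = frozenset(CATEGORY_WEIGHTS) | {"DD"}

#: Maximum per-species weight (all-extinct worst case divisor is 5N).
MAX_WEIGHT = 5


def category_weight(code: str) -> int:
    """Weight of one IUCN category code (LC=0 ... CR=4, EW=EX=5)."""
    code = code.strip().upper()
    if code == "DD":
        raise UsageError("DD has no weight; exclude Data Deficient species upstream")
    try:
        return CATEGORY_WEIGHTS[code]
    except KeyError:
        raise UsageError(f"unknown IUCN category code {code!r}") from None


def _weights_matrix(table: pd.DataFrame, dd_weight: int | None) -> np.ndarray:
    """Species × dates weight matrix; NaN where DD is excluded."""
    arr = table.to_numpy(dtype=object)
    out = np.empty(arr.shape, dtype=float)
    for idx, code in np.ndenumerate(arr):
        c = str(code).strip().upper()
        if c not in VALID_CODES:
            raise UsageError(f"unknown IUCN category code {code!r}")
        if c == "DD":
            out[idx] = np.nan if dd_weight is None else dd_weight
        else:
            out[idx] = CATEGORY_WEIGHTS[c]
    return out


def _index_from_weights(w: np.ndarray) -> np.ndarray:
    """Per-date RLI from a species × dates weight matrix (NaN = excluded)."""
    n = np.sum(np.isfinite(w), axis=0)
    if np.any(n == 0):
        raise DataError("no assessable species (all Data Deficient) at some date")
    return 1.0 - np.nansum(w, axis=0) / (MAX_WEIGHT * n)


def rli_point(categories, dd_weight: int | None = None) -> float:
    """RLI for a single assessment date from a sequence of category codes."""
    codes = pd.DataFrame({"d": list(categories)})
    w = _weights_matrix(codes, dd_weight)
    return float(_index_from_weights(w)[0])


@dataclass
class RliResult:
    """Per-date RLI values with bootstrap limits and change significance."""

    dates: list[str]
    values: np.ndarray  # point estimates per date
    lower: np.ndarray  # 2.5 percentile per date
    upper: np.ndarray  # 97.5 percentile per date
    significant: np.ndarray  # bool per consecutive date pair (len = dates - 1)
    reps: int
    replicates: np.ndarray | None = None  # (reps, dates) bootstrap indices

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"rli": self.values, "lower": self.lower, "upper": self.upper},
            index=pd.Index(self.dates, name="date"),
        )


def rli_bootstrap(
    table: pd.DataFrame,
    reps: int = 1000,
    seed: int | None = None,
    dd_weight: int | None = None,
    change: str = "consecutive",
) -> RliResult:
    """RLI per date with bootstrap confidence limits.

    ``table`` is species (rows) × assessment dates (columns) of category
    codes.  Each replicate resamples whole species rows with replacement
    to the original species count and recomputes the per-date index;
    limits are the 2.5/97.5 percentiles.  For each date pair (consecutive
    pairs by default, or first-vs-last with ``change="endpoints"``), the
    change is significant when strictly more than 95% of replicate
    changes share the sign of the observed change; an observed change of
    exactly zero is never significant.
    """
    if reps < 2:
        raise UsageError("need at least 2 bootstrap replicates")
    if change not in ("consecutive", "endpoints"):
        raise UsageError("change must be 'consecutive' or 'endpoints'")
    w = _weights_matrix(table, dd_weight)
    point = _index_from_weights(w)
    n_sp, n_dates = w.shape
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n_sp, size=(reps, n_sp))
    boot = np.empty((reps, n_dates))
    for r in range(reps):
        boot[r] = _index_from_weights(w[idx[r]])
    lower = np.percentile(boot, 2.5, axis=0)
    upper = np.percentile(boot, 97.5, axis=0)
    if change == "consecutive":
        pairs = [(i, i + 1) for i in range(n_dates - 1)]
    else:
        pairs = [(0, n_dates - 1)] if n_dates > 1 else []
    sig = np.zeros(len(pairs), dtype=bool)
    for k, (a, b) in enumerate(pairs):
        true_delta = point[b] - point[a]
        if true_delta == 0:
            continue
        deltas = boot[:, b] - boot[:, a]
        same_sign = np.sum(np.sign(deltas) == np.sign(true_delta))
        sig[k] = same_sign > 0.95 * reps
    return RliResult(
        dates=[str(c) for c in table.columns],
        values=point,
        lower=lower,
        upper=upper,
        significant=sig,
        reps=reps,
        replicates=boot,
    )


def rli_multi(
    table: pd.DataFrame,
    groups,
    reps: int = 1000,
    seed: int | None = None,
    dd_weight: int | None = None,
) -> dict[str, RliResult | None]:
    """RLI with bootstrap for several species groups at once.

    ``groups`` is a per-species label sequence aligned with the table
    rows.  Groups are processed independently in order of first
    appearance; a group with no assessable species yields None with a
    warning rather than failing the whole call.
    """
    groups = np.asarray(list(groups))
    if len(groups) != len(table):
        raise UsageError("group labels must align with table rows")
    seen = list(dict.fromkeys(groups.tolist()))
    rng = np.random.default_rng(seed)
    out: dict[str, RliResult | None] = {}
    for g in seen:
        sub = table.iloc[np.nonzero(groups == g)[0]]
        try:
            out[g] = rli_bootstrap(
                sub, reps=reps, seed=int(rng.integers(2**31)), dd_weight=dd_weight
            )
        except DataError as e:
            warnings.warn(f"group {g!r}: {e}")
            out[g] = None
    return out


@dataclass
class SampledRliResult:
    """Accumulation curve of sampled-RLI error against subsample size."""

    sizes: np.ndarray  # subsample sizes 2..N
    error_quantile: np.ndarray  # 95th pct of worst-date |SRLI - RLI| per size
    minimal_n: int  # smallest size meeting max_error (N if none)
    max_error: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"n_species": self.sizes, "error_q95": self.error_quantile}
        )


def rli_sampled(
    table: pd.DataFrame,
    max_error: float = 0.05,
    reps: int = 1000,
    seed: int | None = None,
    dd_weight: int | None = None,
    quantile: float = 95.0,
) -> SampledRliResult:
    """How many species are enough for a Sampled Red List Index (SRLI)?

    For each subsample size n = 2..N, draws ``reps`` random species
    subsets without replacement, computes the absolute deviation of the
    subsample index from the full-table RLI at each date, and records
    the ``quantile`` percentile of the worst-date deviation.  Returns
    the error curve and the smallest n whose error quantile is within
    ``max_error`` (N if none smaller qualifies).
    """
    if max_error <= 0:
        raise UsageError("max_error must be positive")
    w = _weights_matrix(table, dd_weight)
    n_sp = len(w)
    if n_sp < 3:
        raise DataError("need at least 3 species for a sampled-RLI curve")
    if max_error >= 1:
        warnings.warn("max_error >= 1 is met trivially by any subsample")
    full = _index_from_weights(w)
    rng = np.random.default_rng(seed)
    sizes = np.arange(2, n_sp + 1)
    errq = np.empty(len(sizes))
    for k, n in enumerate(sizes):
        if n == n_sp:
            errq[k] = 0.0  # subsample is the whole population
            continue
        worst = np.empty(reps)
        for r in range(reps):
            pick = rng.choice(n_sp, size=n, replace=False)
            worst[r] = np.max(np.abs(_index_from_weights(w[pick]) - full))
        errq[k] = np.percentile(worst, quantile)
    qualifying = sizes[errq <= max_error]
    minimal_n = int(qualifying.min()) if len(qualifying) else n_sp
    return SampledRliResult(sizes, errq, minimal_n, max_error)


def read_category_table(path) -> tuple[pd.DataFrame, np.ndarray | None]:
    """Read a category table CSV.

    Columns: optional ``group``, required ``species``, then one column
    per assessment date.  Returns (table indexed by species, groups or
    None).
    """
    df = pd.read_csv(path, dtype=str)
    cols = [c.lower() for c in df.columns]
    groups = None
    if "group" in cols:
        groups = df.iloc[:, cols.index("group")].to_numpy()
        df = df.drop(columns=df.columns[cols.index("group")])
        cols = [c.lower() for c in df.columns]
    if "species" in cols:
        df = df.set_index(df.columns[cols.index("species")])
    if df.shape[1] < 1:
        raise DataError(f"{path}: no assessment-date columns")
    return df, groups
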