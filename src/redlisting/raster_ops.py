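"""Raster utilities: dimensionality reduction and habitat-patch mapping.

:func:`reduce_layers` guards species distribution models against
overfitting when predictors outnumber what the records can support,
either by PCA (returning component-score rasters) or by pruning highly
correlated layers.  :func:`map_habitat` maps a habitat specialist's
range as the union of habitat patches known to be occupied — often the
best range estimate when the habitat is well mapped but the species
records are few.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.decomposition import PCA

from .errors import DataError, UsageError
from .occurrences import OccurrenceSet
from .raster import RasterLayer, RasterStack
from .range_metrics import RangeValue, range_value


def reduce_layers(
    stack: RasterStack,
    method: str = "pca",
    n: int | None = None,
    threshold: float = 0.7,
) -> RasterStack:
    """Reduce a stack of quantitative layers to fewer dimensions.

    method="pca"
        Layers are standardized over their common data cells, a PCA is
        fitted, and the first ``n`` component-score rasters are returned
        (NoData propagated).
    method="cor"
        Iteratively drops the layer with the highest mean absolute
        pairwise correlation until all pairwise ``|r| < threshold``
        (ties: the lowest layer index is dropped first), returning the
        surviving original layers.

    Categorical or constant layers cannot enter either reduction and
    raise an error naming the layer.
    """
    for lyr in stack:
        if lyr.categorical:
            raise DataError(f"layer {lyr.name!r} is categorical; exclude it before reduction")
    if len(stack) < 2:
        raise UsageError("need at least 2 layers to reduce")
    mask = stack.common_mask()
    table = np.column_stack([lyr.values[mask] for lyr in stack])
    sd = table.std(axis=0)
    for i in np.nonzero(sd == 0)[0]:
        raise DataError(f"layer {stack.names[i]!r} is constant over data cells")

    if method == "pca":
        if n is None:
            n = 2
        if not 1 <= n <= len(stack):
            raise UsageError(f"n must be in 1..{len(stack)}")
        z = (table - table.mean(axis=0)) / sd
        scores = PCA(n_components=n).fit_transform(z)
        out = []
        for k in range(n):
            grid = np.full(stack.grid.shape, np.nan)
            grid[mask] = scores[:, k]
            out.append(stack.grid.copy_with(grid, name=f"PC{k + 1}", categorical=False))
        return RasterStack(out)

    if method == "cor":
        keep = list(range(len(stack)))
        corr = np.corrcoef(table, rowvar=False)
        while len(keep) > 1:
            sub = np.abs(corr[np.ix_(keep, keep)])
            np.fill_diagonal(sub, 0.0)
            if sub.max() < threshold:
                break
            mean_abs = sub.mean(axis=1)
            worst = int(np.argmax(mean_abs))  # argmax takes the first max: lowest index
            keep.pop(worst)
        return RasterStack([stack[i] for i in keep])

    raise UsageError(f"unknown reduction method {method!r}")


def label_patches(habitat: RasterLayer, connectivity: int = 8) -> RasterLayer:
    """Label connected habitat patches.

    Returns an integer-labelled raster (0 = non-habitat, k ≥ 1 = patch
    id).  Queen (8-neighbour) connectivity by default: diagonally
    touching habitat cells belong to the same patch.
    """
    if connectivity not in (4, 8):
        raise UsageError("connectivity must be 4 or 8")
    structure = np.ones((3, 3)) if connectivity == 8 else ndimage.generate_binary_structure(2, 1)
    binary = habitat.mask & (habitat.values > 0)
    labels, _ = ndimage.label(binary, structure=structure)
    out = np.where(habitat.mask, labels.astype(float), np.nan)
    return habitat.copy_with(out, name=f"{habitat.name}_patches", categorical=True)


@dataclass
class HabitatRange:
    """Result of :func:`map_habitat`."""

    presence: RasterLayer  # binary: cells of occupied patches
    raw: RangeValue  # EOO/AOO from the records themselves
    modelled: RangeValue  # EOO/AOO from the occupied-patch raster
    occupied_patches: set[int]


def map_habitat(
    records: OccurrenceSet,
    habitat: RasterLayer,
    move: bool = False,
    connectivity: int = 8,
) -> HabitatRange:
    """Map the habitat patches occupied by at least one record.

    ``habitat`` is a 0/1 raster (NoData allowed).  With ``move=True``,
    records on non-habitat cells are first snapped to the nearest
    habitat cell (use when off-habitat records reflect georeferencing
    error rather than lost subpopulations).  Raw EOO/AOO come from the
    (possibly moved) records, modelled EOO/AOO from the occupied-patch
    raster.
    """
    labels = label_patches(habitat, connectivity)
    if move:
        from .qc import move_to_valid

        habitat_only = habitat.copy_with(
            np.where(habitat.mask & (habitat.values > 0), 1.0, np.nan)
        )
        records = move_to_valid(records, habitat_only)
    ids = labels.sample(records.coords)
    occupied = {int(v) for v in ids if np.isfinite(v) and v > 0}
    if not occupied:
        raise DataError("species occupies no habitat patch")
    pres = np.where(
        habitat.mask,
        np.isin(np.nan_to_num(labels.values, nan=0.0), sorted(occupied)).astype(float),
        np.nan,
    )
    presence = habitat.copy_with(pres, name=f"{habitat.name}_occupied", categorical=False)
    return HabitatRange(
        presence=presence,
        raw=range_value(records),
        modelled=range_value(presence),
        occupied_patches=occupied,
    )
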