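import numpy as np
import pytest

from redlisting import OccurrenceSet, RasterLayer, RasterStack
from redlisting import fixtures


@pytest.fixture
def square_records() -> OccurrenceSet:
    """Four metric points at the corners of a 10 km x 10 km square."""
    return OccurrenceSet(
        np.array([[0.0, 0.0], [10_000.0, 0.0], [10_000.0, 10_000.0], [0.0, 10_000.0]]),
        crs="metric",
    )


@pytest.fixture(scope="session")
def island():
    """The default island-spider worked example (landscape, records, species)."""
    return fixtures.island_spider(seed=42)


@pytest.fixture
def small_dem() -> RasterLayer:
    """5x5 synthetic cone DEM, 1-km cells, top-left origin at (0, 5000)."""
    yy, xx = np.mgrid[0:5, 0:5]
    vals = 2000.0 - 300.0 * np.hypot(yy - 2, xx - 2)
    return RasterLayer(vals, 1000.0, (0.0, 5000.0), name="dem")


def make_layer(values, cell_size=1000.0, origin=None, **kw) -> RasterLayer:
    values = np.asarray(values, dtype=float)
    if origin is None:
        origin = (0.0, values.shape[0] * cell_size)
    return RasterLayer(values, cell_size, origin, **kw)


def make_stack(grids, **kw) -> RasterStack:
    return RasterStack([make_layer(g, name=f"env{i+1}", **kw) for i, g in enumerate(grids)])
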