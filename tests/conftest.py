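import numpy as np
import pytest
from hypothesis import settings

from somfuse.raster import GridGeometry, RasterGrid

settings.register_profile("derandomized", derandomize=True, deadline=None)
settings.load_profile("derandomized")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_grid(values, mask=None, x0=500000.0, y0=4100000.0, pixel=30.0, crs=32650):
    values = np.asarray(values, dtype=float)
    geom = GridGeometry(x0=x0, y0=y0, dx=pixel, dy=-pixel,
                        rows=values.shape[0], cols=values.shape[1])
    return RasterGrid(values=values, geometry=geom, crs=crs, mask=mask)


@pytest.fixture
def grid_factory():
    return make_grid
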