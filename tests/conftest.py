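import numpy as np
import pytest

from phyloniche.rasters import GridSpec, Raster, RasterStack
from phyloniche.simulate import gaussian_random_field


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_spec():
    return GridSpec(n_rows=5, n_cols=4, cell_size=1.0, x_ll=0.0, y_ll=0.0)


@pytest.fixture
def flat_stack(small_spec):
    """Single constant-ish layer (tiny gradient avoids degeneracy)."""
    vals = np.full((5, 4), 10.0) + np.arange(20).reshape(5, 4) * 1e-12
    return RasterStack([Raster(small_spec, vals, "flat")])


def make_climate_stack(n_rows=60, n_cols=60, n_layers=1, seed=0, lo=10.0, hi=95.0):
    rng = np.random.default_rng(seed)
    spec = GridSpec(n_rows=n_rows, n_cols=n_cols, cell_size=0.05, x_ll=0.0, y_ll=0.0)
    layers = []
    for i in range(n_layers):
        field = gaussian_random_field(n_rows, n_cols, 4.0, rng)
        layers.append(
            Raster(spec, 0.5 * (lo + hi) + field * (hi - lo) / 6.0, f"bio{i + 1:02d}")
        )
    return RasterStack(layers)


@pytest.fixture
def climate_stack():
    return make_climate_stack()
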