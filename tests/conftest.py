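import numpy as np
import pytest

from bolusmap import DynamicSeries, default_phantom_spec, simulate_series


def make_series(array, dt=1.0, **kw):
    """DynamicSeries from a (t, z, y, x) array with default metadata."""
    return DynamicSeries(intensities=np.asarray(array, dtype=float), dt=dt, **kw)


def curve_series(values, dt=1.0, **kw):
    """Single-voxel series from a 1D time course."""
    arr = np.asarray(values, dtype=float).reshape(-1, 1, 1, 1)
    return DynamicSeries(intensities=arr, dt=dt, **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def random_series(rng):
    return make_series(rng.uniform(0, 10, size=(7, 2, 6, 6)), dt=0.5)


@pytest.fixture(scope="session")
def noiseless_phantom():
    spec = default_phantom_spec()
    series, truth = simulate_series(spec)
    return spec, series, truth
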