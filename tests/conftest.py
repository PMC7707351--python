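import numpy as np
import pytest

from dosemine.dose_accum import DoseGrid


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def smooth_grid(rng):
    """A smooth random dose field on a small lattice (4 mm voxels)."""
    shape = (24, 24, 18)
    ax = [np.linspace(0, 2 * np.pi, s) for s in shape]
    gx, gy, gz = np.meshgrid(*ax, indexing="ij")
    vals = 30.0 + 20.0 * np.sin(gx) * np.cos(gy) * np.sin(gz + 0.3)
    vals += rng.normal(0, 0.5, shape)
    return DoseGrid(vals, [4.0, 4.0, 4.0])
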