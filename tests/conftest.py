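import numpy as np
import pytest

import snapshotpa as sp


@pytest.fixture(scope="session")
def params():
    return sp.AcousticParams()


@pytest.fixture(scope="session")
def tiny_grid():
    # 3 x 3 x 5 voxels, 10 mm in front of the relay entrance
    return sp.centered_grid((2.0, 2.0, 1.2), (1.0, 1.0, 0.3), standoff_mm=10.0)


@pytest.fixture(scope="session")
def tiny_dict(params, tiny_grid):
    return sp.build_dictionary(tiny_grid, params, sp.EncoderConfig(seed=3))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
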