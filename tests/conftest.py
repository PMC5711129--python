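import numpy as np
import pytest

import warp4d as w


@pytest.fixture
def rng():
    return np.random.default_rng(20140978)


@pytest.fixture
def small_grid():
    return w.Grid3D((12, 10, 14), (2.0, 2.5, 3.0), (-10.0, 5.0, -20.0))


@pytest.fixture
def random_volume(small_grid, rng):
    return w.ScalarVolume(small_grid, rng.normal(50, 30, small_grid.shape), "HU")


@pytest.fixture(scope="session")
def default_study():
    """One full pipeline run on the default phantom, shared across tests.

    Ten generated phases, nine deformable registrations, dose warping and
    accumulation for every phase subset, metrics for every structure.
    """
    cfg = w.StudyConfig(seed=1)
    return w.run_study(cfg)


@pytest.fixture(scope="session")
def zero_motion_study():
    """Pipeline run with zero breathing amplitude (no 3D/4D gap expected)."""
    cfg = w.StudyConfig(seed=1, amplitude_mm=(0.0, 0.0, 0.0),
                        grid_shape=(64, 64, 64))
    return w.run_study(cfg)
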