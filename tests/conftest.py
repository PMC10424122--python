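import numpy as np
import pytest

from couplemap.preproc import Volume4D
from couplemap.synth import CohortConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20230731)


@pytest.fixture
def tiny_cohort_config():
    """A fast-to-generate cohort: 8^3 grid, short series, default effects."""
    return CohortConfig(n_per_group=(3, 3, 3), grid_shape=(8, 8, 8),
                        n_timepoints=32, seed=11)


def make_volume(data: np.ndarray, tr_s: float = 2.2,
                voxel_mm: float = 3.0) -> Volume4D:
    affine = np.diag([voxel_mm] * 3 + [1.0])
    return Volume4D(data, affine, tr_s)


@pytest.fixture
def make_vol():
    return make_volume
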