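import numpy as np
import pytest

from suscnet import KDEConfig, SusceptibilityMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def fast_kde():
    """Coarser quadrature grid used to keep whole-pipeline tests quick."""
    return KDEConfig(grid_points=256)


@pytest.fixture
def random_matrix(rng):
    """A valid 10-region similarity matrix with distinct off-diagonal weights."""
    n = 10
    vals = rng.uniform(0.05, 0.95, size=(n, n))
    vals = (vals + vals.T) / 2
    np.fill_diagonal(vals, 1.0)
    return SusceptibilityMatrix(
        subject_id="sub-0", region_ids=list(range(1, n + 1)), values=vals
    )
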