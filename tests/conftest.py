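import numpy as np
import pytest

from diurnet import DesignGrid, generate_periodic_tensor


@pytest.fixture(scope="session")
def grid() -> DesignGrid:
    """Default two-day design: hours 2..46 every 4 h, three replicates."""
    return DesignGrid()


@pytest.fixture(scope="session")
def cosine_tensor(grid):
    """Three noiseless unit cosines with known phases 10, 0 and 6 h."""
    tensor, truth = generate_periodic_tensor(
        3, grid, noise_sd=0.0, seed=1,
        phases=np.array([10.0, 0.0, 6.0]),
        amplitudes=np.array([1.0, 1.0, 1.0]),
        baselines=np.array([2.0, 2.0, 2.0]))
    return tensor, truth
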