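import numpy as np
import pytest

from tesim.config import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_config():
    """A tiny, fast configuration for object-level tests."""
    return SimulationConfig(N=20, chrom_length=1000, n_chroms=2, u=0.01,
                            s=1e-3, r=0.0, n0=4, max_generations=50)
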