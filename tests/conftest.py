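import numpy as np
import pytest

from aflpcap import synthdata


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def uniform_genome():
    """1 Mb i.i.d.-uniform genome (module-scoped generation is cheap)."""
    return synthdata.simulate_genome(1_000_000, gc=0.5, seed=99)
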