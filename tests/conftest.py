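import numpy as np
import pytest

from insulscope.genome import GenomeSpec
from insulscope.hic import NORMALIZED, ContactMatrix


@pytest.fixture
def genome():
    return GenomeSpec({"chrSim": 1_000_000}, 2000)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def normalized_matrix(values: np.ndarray, resolution: int = 2000) -> ContactMatrix:
    """Wrap a symmetric array as an already-normalized matrix for tests."""
    return ContactMatrix("chrSim", resolution, values, state=NORMALIZED)
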