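import sys
from pathlib import Path

import numpy as np
import pytest

# make tests/oracles.py importable regardless of invocation directory
sys.path.insert(0, str(Path(__file__).parent))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_pair(rng):
    """A seeded (u, f) pair of small random fields."""
    return rng.random((7, 7)), rng.random((7, 7))
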