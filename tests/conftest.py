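import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `helpers` importable

from seqrecog.grid import make_grid


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def small_grid():
    """6x6x6 full box, 26-connectivity."""
    return make_grid((6, 6, 6))


@pytest.fixture
def tiny_grid():
    return make_grid((3, 3, 3))
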