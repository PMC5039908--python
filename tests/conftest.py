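import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from seqppi.alphabet import RESIDUES


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_sequence(rng):
    """Factory for random sequences over the 20 standard residues."""

    def make(length: int) -> str:
        return "".join(rng.choice(list(RESIDUES), size=length))

    return make
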