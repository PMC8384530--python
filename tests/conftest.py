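import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # reference_mpa, _oracles

from mpacnn.cnn import ArchitectureSpec


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_arch():
    """8x8 input, one 2-filter conv stage, 3-unit dense head: 149 parameters."""
    return ArchitectureSpec(input_shape=(8, 8, 1), conv_filters=(2,),
                            dense_units=(3,), num_classes=2, dropout_rate=0.0)
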