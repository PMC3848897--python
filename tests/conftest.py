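import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle module

from mrmsim import Neighborhood, SimulationParams, default_types


@pytest.fixture
def tiny_params():
    """A fast 16x16 four-type configuration for behavioural tests."""
    return SimulationParams(
        L=16,
        types=default_types(4),
        r_spec=Neighborhood("von_neumann"),
        h_spec=Neighborhood("moore", 3),
        t_max=20,
        seed=42,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
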