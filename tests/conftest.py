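import numpy as np
import pytest

from allt1.signal import SequenceTiming
from allt1.phantom import make_phantom


@pytest.fixture(scope="session")
def timing() -> SequenceTiming:
    """Standard sequence timing: TR 2.9624 ms, Td 3 s, 1476 spokes / 6 bins."""
    return SequenceTiming()


@pytest.fixture(scope="session")
def small_phantom(timing):
    """Deterministic 32x32 three-tissue phantom shared across tests."""
    return make_phantom((32, 32), n_tissues=3, seed=11, timing=timing)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
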