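import numpy as np
import pytest

from ambytc import StudyDesign


@pytest.fixture
def design():
    """Small study design used across tests."""
    return StudyDesign(n_probesets=60, seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
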