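import numpy as np
import pytest

from cfnipt import ChromSizes, default_genome


@pytest.fixture(scope="session")
def genome():
    """The packaged toy genome (shared; treat as read-only)."""
    return default_genome()


@pytest.fixture
def toy_sizes():
    return ChromSizes({"chrA": 1000, "chrB": 500})


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
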