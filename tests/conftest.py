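import numpy as np
import pytest

from salrmix.model import PotentialParams


@pytest.fixture(scope="session")
def params():
    """The studied parametrisation: z_a=10, z_r=0.5, alpha=0.1."""
    return PotentialParams()


@pytest.fixture()
def rng():
    return np.random.default_rng(20220228)
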