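import numpy as np
import pytest

from serialreg.synth import generate_base_texture


@pytest.fixture(scope="session")
def texture128():
    return generate_base_texture((128, 128), seed=0)


@pytest.fixture(scope="session")
def texture256():
    return generate_base_texture((256, 256), seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
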