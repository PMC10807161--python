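import numpy as np
import pytest

from vterisk import load_instrument


@pytest.fixture(scope="session")
def instrument():
    """The packaged 39-indicator VTE instrument."""
    return load_instrument()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
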