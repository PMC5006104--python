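import numpy as np
import pytest

from twopop import ModelSpec, TransferParams


@pytest.fixture(scope="session")
def transfer():
    return TransferParams()


@pytest.fixture()
def quiet_spec():
    """Low-coupling circuit with the transient-protocol background drive."""
    return ModelSpec.make(0.17, 0.01, Io=0.32, sigma_noise=0.001)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
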