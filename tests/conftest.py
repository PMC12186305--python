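import numpy as np
import pytest

from lungmli import ParenchymaSpec, control_spec, generate_parenchyma


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def parenchyma_sample():
    """One deterministic 128x128 parenchyma image with its truth mask."""
    return generate_parenchyma(control_spec(seed=7))


@pytest.fixture(scope="session")
def noiseless_sample():
    return generate_parenchyma(control_spec(seed=7, noise_sd=0.0))
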