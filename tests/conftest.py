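import numpy as np
import pytest

from synapsefret.models import KineticModel


@pytest.fixture
def default_model() -> KineticModel:
    """Generator defaults: intact-substrate kinetics with full photophysics."""
    return KineticModel()


@pytest.fixture
def clean_model() -> KineticModel:
    """Noiseless, bleach-free, correction-free model for exactness checks."""
    return KineticModel(
        noise_sigma=0.0,
        beta_true=0.0,
        direct_excitation=0.0,
        bleach_rate_donor=0.0,
        bleach_rate_acceptor=0.0,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
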