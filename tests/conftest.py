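import numpy as np
import pytest

from dmribench import diffusion_model as dm
from dmribench import change_models as cm

# Harness-wide study conditions: two-shell 105-measurement protocol, SNR 100,
# change models trained on 20k prior draws with observed-baseline conditioning.
TRAIN_N = 20_000
NOISE_SIGMA = 0.01


@pytest.fixture(scope="session")
def protocol():
    return dm.make_ukb_protocol(seed=1)


@pytest.fixture(scope="session")
def full_models(protocol):
    """Change models for all 8 standard-model parameters (shared, expensive)."""
    return cm.train_pattern_set(dm.StandardModel(), protocol, n=TRAIN_N,
                                seed=7, noise_sigma=NOISE_SIGMA)


@pytest.fixture(scope="session")
def constrained_models(protocol):
    """Change models for the 4 constrained-model parameters."""
    return cm.train_pattern_set(dm.ConstrainedModel(), protocol, n=TRAIN_N,
                                seed=7, noise_sigma=NOISE_SIGMA)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
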