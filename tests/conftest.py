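import numpy as np
import pytest
from hypothesis import settings

import novelnet as nn

settings.register_profile("ci", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("ci")

SEED = 1


@pytest.fixture(scope="session")
def tiny():
    """A 200 E / 50 I network with default (uncompensated) parameters."""
    config, conn, stimset = nn.make_fixture_network(0.05, seed=SEED,
                                                    n_stimuli=3)
    config["sim"].seed = SEED
    return config, conn, stimset


@pytest.fixture()
def blank_protocol():
    def make(duration_ms):
        return nn.Protocol([nn.StimulusEpoch(0.0, duration_ms, None,
                                             tag="blank")])
    return make


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(SEED)
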