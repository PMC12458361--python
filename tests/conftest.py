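import numpy as np
import pytest

import tdcircuit as tc


@pytest.fixture(scope="session")
def pattern_session_gamma05():
    """Inputs and one noisy neuron response at gamma*=0.5, SNR 10 (1 kHz)."""
    inputs, neurons = tc.generate_pattern_responses(
        gamma_true=0.5, snr=10.0, n_neurons=1, seed=42)
    return inputs, neurons[0]


@pytest.fixture(scope="session")
def optotag_session():
    return tc.simulate_optotag_session(n_tagged=6, n_untagged=6, seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
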