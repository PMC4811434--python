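import numpy as np
import pytest

from oscistim.synthetic_data import SyntheticTrialConfig, generate_trial, make_layout


@pytest.fixture(scope="session")
def layout44():
    return make_layout(4, 4, 10.0)


@pytest.fixture(scope="session")
def trial_ec(layout44):
    """One eyes-closed synthetic trial with artifacts, reused read-only."""
    return generate_trial(SyntheticTrialConfig(seed=11), layout44, "eyes_closed")


@pytest.fixture(scope="session")
def small_net_kwargs():
    """Network arguments small enough for sub-second unit-test runs."""
    from oscistim.network_model import NetworkParams, StimulusProtocol

    params = NetworkParams(N=20, seed=0, dt=0.5)
    protocol = StimulusProtocol(pre_duration=1.0, stim_duration=1.0, post_duration=1.0)
    return {"params": params, "protocol": protocol}
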