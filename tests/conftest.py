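import numpy as np
import pytest

from impactchain import build_default_chain, simulate, synth_half_sine


@pytest.fixture(scope="session")
def default_chain():
    return build_default_chain()


@pytest.fixture(scope="session")
def half_sine():
    return synth_half_sine()


@pytest.fixture(scope="session")
def reference_sim(default_chain, half_sine):
    """Reference-configuration simulation, shared across tests."""
    return simulate(default_chain, half_sine)


@pytest.fixture(scope="session")
def zero_pulse():
    from impactchain import ForcePulse

    return ForcePulse(samples=np.zeros(641), sample_rate=800e3)
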