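import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from ifgc import netsim

settings.register_profile(
    "ci", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    return netsim.NeuronParams()


@pytest.fixture(scope="session")
def two_neuron_net():
    return netsim.two_neuron_network()


@pytest.fixture(scope="session")
def two_neuron_record(two_neuron_net, params):
    """One 120-s intermediate-regime recording of the unidirectional pair,
    shared across tests that only read it."""
    drive = netsim.DriveSpec(rate=0.1, strength=0.07, seed=0)
    return netsim.simulate(two_neuron_net, params, drive, duration=120_000.0)


@pytest.fixture(scope="session")
def long_two_neuron_record(two_neuron_net, params):
    """300-s recording for diagnostics needing more triggers."""
    drive = netsim.DriveSpec(rate=0.08, strength=0.07, seed=6)
    return netsim.simulate(two_neuron_net, params, drive, duration=300_000.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
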