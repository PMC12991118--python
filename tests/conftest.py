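import numpy as np
import pytest

from photoplast import synth
from photoplast.bci import BCIConfig, Thresholds


@pytest.fixture(scope="session")
def small_circuit():
    """200-neuron ground-truth circuit shared across read-only tests."""
    return synth.sample_circuit(synth.CircuitConfig(n_neurons=200), seed=11)


@pytest.fixture(scope="session")
def small_session(small_circuit):
    return synth.simulate_session(small_circuit, seed=21)


@pytest.fixture(scope="session")
def photostim_block(small_circuit):
    groups = synth.sample_groups(small_circuit.positions, n_groups=60,
                                 group_size=10, seed=31)
    raw, groups = synth.simulate_photostim_block(
        small_circuit, groups, repeats=15, seed=41
    )
    return raw, groups


@pytest.fixture
def default_cfg():
    return BCIConfig()


@pytest.fixture
def unit_thresholds():
    return Thresholds(FL=0.0, FU=2.0)
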