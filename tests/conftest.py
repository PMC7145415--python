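"""Shared fixtures: synthetic GGN morphology, compartmental model, PN trains.

Session scope keeps the expensive objects (morphology generation, inhibition
calibration) shared across the suite.
"""

import numpy as np
import pytest

from mbsim.cable import BiophysicsParams
from mbsim.morphology import compartmentalize, generate_synthetic_ggn
from mbsim.experiments import odor_pn_trains, spontaneous_trains


@pytest.fixture(scope="session")
def ggn_morph():
    return generate_synthetic_ggn(seed=1)


@pytest.fixture(scope="session")
def bio():
    return BiophysicsParams()


@pytest.fixture(scope="session")
def ggn_model(ggn_morph, bio):
    return compartmentalize(ggn_morph, bio)


@pytest.fixture(scope="session")
def spont_trains():
    return spontaneous_trains(seed=1)


@pytest.fixture(scope="session")
def shifting_trains():
    return odor_pn_trains("shifting", seed=1)


@pytest.fixture(scope="session")
def fixed_trains():
    return odor_pn_trains("fixed", seed=1)


@pytest.fixture(scope="session")
def calibrated_scale(ggn_model, spont_trains):
    """Graded-gbar scale holding the median KC near -60 mV (n_kc = 500)."""
    from mbsim.network import NetworkConfig, build_network, calibrate_kc_inhibition
    net = build_network(NetworkConfig(n_kc=500, seed=1), ggn_model, seed=1)
    return calibrate_kc_inhibition(net, spont_trains, duration=1500.0)


def spike_count(t, v, threshold=0.0, refractory=2.0):
    """Spike counting helper used by several electrophysiology tests."""
    up = np.flatnonzero((v[:-1] < threshold) & (v[1:] >= threshold))
    n, last = 0, -np.inf
    for i in up:
        if t[i + 1] - last >= refractory:
            n += 1
            last = t[i + 1]
    return n
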