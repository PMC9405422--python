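"""Shared fixtures: circuit parameter sets and seeded synthetic sessions.

Sessions are generated at the 5 kHz fast profile to keep the suite quick;
noise SDs are defined at the 50 kHz acquisition bandwidth and scale down
automatically (see NoiseConfig).
"""

import numpy as np
import pytest

from cacc import (NetworkEventConfig, NeuronConfig, NoiseConfig,
                  PatchCircuitParams, StimulusProtocol, simulate_dual,
                  simulate_gaba_experiment, simulate_membrane,
                  simulate_network_session)

FAST_RATE = 5000.0


@pytest.fixture(scope="session")
def example_cell() -> PatchCircuitParams:
    """Fitted circuit of the single example cell (C_elec fixed at 7 pF)."""
    return PatchCircuitParams(R_seal=55.6, R_patch=7.3, C_patch=0.8, C_elec=7.0)


@pytest.fixture(scope="session")
def median_cell() -> PatchCircuitParams:
    """Group-median circuit parameters."""
    return PatchCircuitParams(R_seal=15.4, R_patch=4.9, C_patch=0.8, C_elec=7.0)


@pytest.fixture(scope="session")
def psp_session(median_cell):
    """120 s resting dual recording with spontaneous PSPs (seeded)."""
    neuron = NeuronConfig()
    bundle = simulate_membrane(neuron, None, 120.0, FAST_RATE, seed=11)
    return simulate_dual(bundle, median_cell, NoiseConfig(), seed=211)


@pytest.fixture(scope="session")
def ap_session(median_cell):
    """60 s dual recording with step-evoked action potentials (seeded)."""
    neuron = NeuronConfig(psp_rate=0.0)
    protocols = [StimulusProtocol(kind="step", onset=2.0 + 10.0 * i,
                                  offset=2.5 + 10.0 * i, amplitude=380.0)
                 for i in range(6)]
    bundle = simulate_membrane(neuron, protocols, 60.0, FAST_RATE, seed=12)
    return simulate_dual(bundle, median_cell, NoiseConfig(), seed=212)


@pytest.fixture(scope="session")
def gdp_session(median_cell):
    """120 s LFP+CA session with giant depolarizing potentials."""
    return simulate_network_session(NetworkEventConfig.gdp(), median_cell,
                                    NoiseConfig(), 120.0, seed=13, rate=FAST_RATE)


@pytest.fixture(scope="session")
def swr_sessions(median_cell):
    """Depolarizing and hyperpolarizing sharp-wave-ripple sessions."""
    dep = simulate_network_session(NetworkEventConfig.swr(depolarizing=True),
                                   median_cell, NoiseConfig(), 120.0,
                                   seed=14, rate=FAST_RATE)
    hyp = simulate_network_session(NetworkEventConfig.swr(depolarizing=False),
                                   median_cell, NoiseConfig(), 120.0,
                                   seed=15, rate=FAST_RATE)
    return dep, hyp


@pytest.fixture(scope="session")
def gaba_bundle(median_cell):
    """Evoked GABA-PSP sweeps at five holding levels."""
    return simulate_gaba_experiment(
        NeuronConfig(), [-90.0, -80.0, -70.0, -60.0, -50.0], 10,
        median_cell, NoiseConfig(), seed=16, rate=FAST_RATE,
    )


def match_events(true_times, detected_times, tol):
    """Count of true events with a detection within ``tol`` seconds."""
    true_times = np.asarray(true_times)
    detected_times = np.asarray(detected_times)
    if detected_times.size == 0:
        return 0
    return int(sum(np.min(np.abs(detected_times - t)) <= tol for t in true_times))
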