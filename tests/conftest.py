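import numpy as np
import pytest

import triplet_hawkes as th

#: Connectivity parameters of the reference simulated study: 1000 neurons,
#: 4:1 E/I, 10% connectivity, g_I = -5 g_E.
PAPER_PARAMS = dict(n=1000, n_e=800, n_i=200, p=0.1, g_e=0.015, g_i=-0.075)


@pytest.fixture(scope="session")
def paper_params():
    return th.RegularParams(**PAPER_PARAMS)


@pytest.fixture(scope="session")
def small_stable_net():
    """A 30-node random (non-Dale) stable matrix for theory cross-checks."""
    rng = np.random.default_rng(7)
    g = rng.normal(0.0, 0.05, (30, 30))
    np.fill_diagonal(g, 0.0)
    types = th.NeuronTypes.block(30, 0)
    net = th.WeightedNetwork(g, types, g_e=1.0, g_i=-1.0)
    assert net.spectral_radius() < 0.9
    return net


@pytest.fixture(scope="session")
def small_er_net():
    params = th.RegularParams(n=60, n_e=48, n_i=12, p=0.15, g_e=0.08, g_i=-0.2)
    return params, th.generate_erdos_renyi(params, seed=11)


@pytest.fixture(scope="session")
def coupled_simulation():
    """One moderately coupled 40-neuron simulation shared across tests.

    120 s of data at the reference kernel; strong enough coupling that
    covariances are visible, weak enough that rectification is negligible.
    """
    params = th.RegularParams(n=40, n_e=32, n_i=8, p=0.3, g_e=0.05, g_i=-0.08)
    net = th.generate_erdos_renyi(params, seed=5)
    kernel = th.KernelSpec(tau=10.0, delay=2.0)
    config = th.SimulationConfig(dt=0.1, duration=121_000.0, burn_in=1000.0,
                                 mu_rate=10.0, seed=42)
    spikes = th.simulate(net, kernel, config)
    rates = th.stationary_rates(net, mu=10.0)
    return net, rates, spikes
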