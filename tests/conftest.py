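import numpy as np
import pytest

from optonet.pipeline import RunConfig, simulate_recording


@pytest.fixture(scope="session")
def small_run():
    """A full-field 20-neuron simulated recording shared across tests.

    Returns (config, protocol, network, raster, calcium, movie).
    """
    cfg = RunConfig(seed=5)
    cfg.protocol.mask_center = None
    cfg.protocol.mask_radius = None
    cfg.network.n_neurons = 20
    return (cfg,) + simulate_recording(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
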