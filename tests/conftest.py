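import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_grid():
    """A small synthetic grid with a planted conditional correlation of 0.3."""
    from peatvpd import synth
    cfg = synth.GridGenConfig(n_lat=8, n_lon=8, target_pcor=0.3, seed=11)
    return synth.gen_gridded(cfg)


@pytest.fixture(scope="session")
def flux_tower():
    """Noiseless monthly flux-tower series with known conductance and uWUE."""
    from peatvpd import synth
    return synth.gen_flux_tower(synth.FluxGenConfig(n_months=120, seed=21))
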