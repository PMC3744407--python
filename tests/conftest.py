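import numpy as np
import pytest

import oscspike as osc


@pytest.fixture(scope="session")
def params_w04():
    """Weak-noise benchmark: slow oscillation, moderate coherence."""
    return osc.CanonicalParams(w=0.4, Q=10.0, sigma_h=0.05, sigma_ou=0.02,
                               tau_ou=0.1)


@pytest.fixture(scope="session")
def train_w04(params_w04):
    """1e5 ISIs at the weak-noise benchmark (canonical units)."""
    return osc.simulate(params_w04, n_spikes=100_001, seed=101)


@pytest.fixture(scope="session")
def train_aff1():
    """4e4 ISIs at the afferent-1 fitted parameters (seconds)."""
    p, cv, rate = osc.table1_params(1)
    return osc.simulate(p, n_spikes=40_001, seed=42)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)
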