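import numpy as np
import pytest

from anionpump import scenarios, synthetic


@pytest.fixture(scope="session")
def wt_cl_series():
    """One noisy wild-type chloride titration (Kd 0.59 mM planted)."""
    return synthetic.gen_titration(scenarios.load_scenario("WT-Cl", seed=11))


@pytest.fixture(scope="session")
def wt_so4_series():
    """One noisy wild-type sulfate titration (Kd 3.6 mM planted)."""
    return synthetic.gen_titration(scenarios.load_scenario("WT-SO4", seed=11))


@pytest.fixture(scope="session")
def wt_photocycle_data():
    """One noisy wild-type transient matrix (taus 0.050/2.2/12 ms planted)."""
    return synthetic.gen_transient(scenarios.load_scenario("WT-NaCl-photocycle", seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
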