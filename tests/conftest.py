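import numpy as np
import pytest

from acehap.synthetic import cold_config, simulate_experiment, simulate_founder


@pytest.fixture(scope="session")
def default_experiment():
    """One full cold-regime experiment at study-condition defaults."""
    return simulate_experiment(cold_config(seed=7))


@pytest.fixture(scope="session")
def default_founder():
    return simulate_founder(cold_config(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
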