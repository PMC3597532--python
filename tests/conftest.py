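import numpy as np
import pytest

from kaiclock import HTD_HU, default_pto, default_ttfl
from kaiclock.simulate import run_experiment


@pytest.fixture(scope="session")
def pto():
    return default_pto()


@pytest.fixture(scope="session")
def ttfl():
    return default_ttfl()


@pytest.fixture(scope="session")
def wildtype_run(pto, ttfl):
    """Settled wild-type reference run of the calibrated TD+/U- model,
    shared across tests (240 h burn-in, 120 h recording)."""
    return run_experiment(pto, ttfl, HTD_HU, burn_in=240.0, record=120.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260924)
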