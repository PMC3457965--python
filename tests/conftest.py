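import numpy as np
import pytest

from hseprobe.thermo import DuplexParams, default_parameter_set


@pytest.fixture(scope="session")
def nn_params():
    return default_parameter_set()


@pytest.fixture(scope="session")
def assay():
    """Default assay conditions: 64 C, 5 uM probe, 3 fM target, 50 mM Na, 1.5 mM Mg."""
    return DuplexParams()


@pytest.fixture()
def rng():
    return np.random.default_rng(20120925)


def random_seq(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))
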