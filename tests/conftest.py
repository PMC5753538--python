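import numpy as np
import pytest

from dtcmr import (
    AcquisitionProtocol,
    LVPhantomSpec,
    build_tensor_field,
    simulate_dwis,
)


@pytest.fixture(scope="session")
def default_spec():
    return LVPhantomSpec()


@pytest.fixture(scope="session")
def truth(default_spec):
    return build_tensor_field(default_spec)


@pytest.fixture(scope="session")
def steam_quiet():
    """STEAM protocol with no RR jitter (noiseless round trips)."""
    return AcquisitionProtocol.steam(rr_jitter_ms=0.0)


@pytest.fixture(scope="session")
def m2se_quiet():
    return AcquisitionProtocol.m2se(rr_jitter_ms=0.0)


@pytest.fixture(scope="session")
def clean_series(truth, steam_quiet):
    """Noiseless, jitter-free STEAM series of the default phantom."""
    return simulate_dwis(truth, steam_quiet, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
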