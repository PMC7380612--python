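import pytest
from hypothesis import HealthCheck, settings

import nozzleflow as nf

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def chitosan():
    """Five-parameter CY law of a printable chitosan hydrogel."""
    return nf.CarreauYasuda5(eta_inf=0.0, eta_0=5807.0, K=5.33, a1=1.35, a2=0.87)


@pytest.fixture(scope="session")
def simplified_fluid():
    """Two-parameter law with a known exact global solution."""
    return nf.SimplifiedCarreauYasuda(eta_0=100.0, K=1.0)


@pytest.fixture(scope="session")
def nozzle_100um():
    return nf.ChannelGeometry(radius=100e-6, length=10e-3)


@pytest.fixture(scope="session")
def needle():
    """21G blunt cannula used in the capillary-rheometry design."""
    return nf.STANDARD_NEEDLE


@pytest.fixture(scope="session")
def alginate_cy3():
    """CY3 parameters of a 2.5% alginate solution from capillary rheometry."""
    return nf.CarreauYasuda3(eta_0=6.8, gammadot_c=27.9, alpha=0.78)
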