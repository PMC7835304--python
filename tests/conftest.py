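import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from nfq.phantom import generate_atlas  # noqa: E402


@pytest.fixture(scope="session")
def atlas():
    """Small shared atlas phantom (48^3, 0.25 mm) for module tests."""
    return generate_atlas((48, 48, 48), (0.25, 0.25, 0.25), seed=1)


@pytest.fixture(scope="session")
def suvr_profile():
    """Uptake-ratio profile on the scale of the EAE group summaries."""
    return {
        "neocortex": 1.0,
        "caudate_putamen": 1.2,
        "hippocampus": 1.6,
        "thalamus": 1.5,
        "cerebellum": 2.4,
        "brainstem": 2.0,
    }


@pytest.fixture(scope="session")
def lesion_request():
    """Lesion fractional volumes (%) on the scale of the EAE group."""
    return {
        "neocortex": 0.5,
        "caudate_putamen": 5.4,
        "hippocampus": 5.7,
        "thalamus": 7.3,
        "cerebellum": 14.5,
        "brainstem": 9.0,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
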