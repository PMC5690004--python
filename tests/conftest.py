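import pytest
from hypothesis import HealthCheck, settings

from ctmaster import SizeFitModel, example_catalog

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def catalog():
    return example_catalog()


@pytest.fixture(scope="session")
def routine_protocol(catalog):
    """The measured reference protocol: 120 kV, 30-400 mA, t 0.4 s, P 0.516, NI 15.5."""
    return catalog.protocol("routine abdomen-pelvis medium adult")


@pytest.fixture(scope="session")
def truth_model():
    """Ground-truth exponential mA-demand curves with a common growth rate."""
    return SizeFitModel.from_params(
        {"p10": (1.8, 0.055), "median": (3.0, 0.055), "p90": (5.0, 0.055)})
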