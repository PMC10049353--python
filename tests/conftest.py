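import pytest
from hypothesis import HealthCheck, settings

from tbsepsis_cea import StructureConfig, calibrate, default_parameters

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def base_params():
    return default_parameters()


@pytest.fixture()
def plain_structure():
    """No delayed empiric therapy, no acute sepsis decrement: the simplest
    structural reading, convenient for hand-computable checks."""
    return StructureConfig(soc_delayed_empiric=False, sepsis_dw_applied=False)


@pytest.fixture(scope="session")
def calibrated(base_params):
    """Calibration of the structural unknowns against the reported results
    (shared across tests; deterministic)."""
    return calibrate(base_params)
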