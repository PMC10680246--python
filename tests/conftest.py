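import pytest
from hypothesis import HealthCheck, settings

from wit2 import PatientProfile, make_arm_params

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def params_a():
    """1:1.5 arm rule set."""
    return make_arm_params("1:1.5")


@pytest.fixture(scope="session")
def params_b():
    """1:1 arm rule set."""
    return make_arm_params("1:1")


@pytest.fixture
def make_profile():
    """Factory for noise-free deterministic patients (overridable fields)."""

    def _make(**overrides) -> PatientProfile:
        fields = dict(
            id="pt",
            weight=66.0,
            height=164.0,
            fbg_base=14.2,
            ppg_base={"breakfast": 17.7, "lunch": 17.7, "dinner": 17.7},
            s_basal=20.0,
            s_bolus=45.0,
            c_spill=4.0,
            lag=0.8,
            noise_sd=0.0,
            nocturnal_dip=0.6,
        )
        fields.update(overrides)
        return PatientProfile(**fields)

    return _make
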