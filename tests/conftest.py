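import pytest
from hypothesis import HealthCheck, settings

from ptml.synthetic import SimConfig, generate_dataset, make_worked_fixture

settings.register_profile(
    "det", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("det")


@pytest.fixture(scope="session")
def worked():
    """Hand-computed 8-record dataset with its expected outputs."""
    return make_worked_fixture()


@pytest.fixture(scope="session")
def small_synth():
    """A 200-reaction synthetic dataset with defaults (noise, missingness,
    misspecified double-carbonylation subset all active)."""
    return generate_dataset(SimConfig(n_reactions=200, seed=11))


@pytest.fixture(scope="session")
def clean_synth():
    """A clean planted dataset: no noise, no missingness, no misspecified
    subset, no imbalance calibration."""
    cfg = SimConfig(
        n_reactions=150,
        noise_sd=0.0,
        missing_rate=0.0,
        dc_extra_noise_sd=0.0,
        class_imbalance=None,
        seed=5,
    )
    return generate_dataset(cfg)
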