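import pytest
from hypothesis import settings

from exorelease.sim import DECOY_LABELS, SimConfig, generate_feature_table

settings.register_profile("suite", derandomize=True, max_examples=30, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def noiseless_sim():
    """Zero replicate noise, zero control background: exact-recovery regime."""
    cfg = SimConfig(
        replicate_cv=0.0,
        control_level=0.0,
        n_released=20,
        decoy_counts={k: 5 for k in DECOY_LABELS},
        seed=11,
    )
    return generate_feature_table(cfg)


@pytest.fixture(scope="session")
def noisy_sim():
    """Default study conditions: 5% replicate CV, medium background present."""
    return generate_feature_table(SimConfig(seed=5))
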