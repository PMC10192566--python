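import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

from seizefuse import presets, build_dataset, generate_patient


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small but trainable synthetic patient (3 episodes, 10 s per state)."""
    spec = presets.scaled_synthetic_spec(seed=11, seg_seconds_per_state=10.0)
    return build_dataset(generate_patient(spec), presets.scaled_preprocess())


@pytest.fixture(scope="session")
def tiny_train_cfg():
    return presets.scaled_train(seed=11, epochs=3)


@pytest.fixture(scope="session")
def branch_cfg():
    return presets.scaled_branch()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
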