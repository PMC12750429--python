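import numpy as np
import pytest

from slrwalk.synthetic import CohortConfig, NoiseParams, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Four-patient signal-level cohort shared by the slower tests."""
    config = CohortConfig(n_per_group=2, seed=7)
    records, truth = generate_cohort(config)
    return records, truth, config


@pytest.fixture(scope="session")
def quiet_cohort():
    """Noise-free cohort: IMU invariants hold exactly."""
    config = CohortConfig(n_per_group=2, seed=11, noise=NoiseParams(accel_g=0.0, gyro_dps=0.0))
    records, truth = generate_cohort(config)
    return records, truth, config


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
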