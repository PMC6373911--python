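import numpy as np
import pytest

from cpetcf.cohort import CohortConfig, generate_patient


@pytest.fixture(scope="session")
def cohort_config() -> CohortConfig:
    """Protocol-default cohort configuration (the study's sample size)."""
    return CohortConfig(n_patients=15, seed=42)


@pytest.fixture(scope="session")
def zero_noise_record(cohort_config):
    """One noiseless synthetic patient: every channel follows its closed form."""
    return generate_patient(cohort_config.zero_noise(), 0)


@pytest.fixture(scope="session")
def noisy_record(cohort_config):
    """One synthetic patient at generator-default noise."""
    return generate_patient(cohort_config, 0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)
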