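import numpy as np
import pytest
from hypothesis import settings

from lapsched import datasets
from lapsched.synthetic import SyntheticConfig, generate_counts

settings.register_profile("default", max_examples=25, derandomize=True, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def dose_response():
    """Published point estimates of the dose-response laws."""
    return datasets.dose_response_params()


@pytest.fixture(scope="session")
def mtd_schedules():
    return datasets.mtd_schedules()


@pytest.fixture(scope="session")
def noisy_counts():
    """One default synthetic dataset (CV 10%, triplicates, seed 7)."""
    return generate_counts(SyntheticConfig(seed=7))


@pytest.fixture(scope="session")
def noiseless_counts():
    return generate_counts(SyntheticConfig(noise_cv=0.0, seed=0))
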