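import numpy as np
import pytest

from cvleak.cohort import GenerativeParams, generate_cohort


@pytest.fixture
def small_params() -> GenerativeParams:
    return GenerativeParams(a=0.5, b=1.0, c=1.0, d=0.1, n_features=5,
                            n_records_per_subject=20, n_subjects=8, seed=11)


@pytest.fixture
def small_cohort(small_params):
    return generate_cohort(small_params)


@pytest.fixture
def zero_noise_cohort():
    return generate_cohort(GenerativeParams(a=0.5, b=0.0, c=0.0, d=0.0,
                                            n_features=3, n_records_per_subject=5,
                                            n_subjects=6, seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
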