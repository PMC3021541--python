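import numpy as np
import pytest

from t2mvpa.simulate import compact_config, generate_cohort


@pytest.fixture(scope="session")
def compact_cohort():
    """One default-condition compact cohort shared across read-only tests."""
    return generate_cohort(compact_config(seed=123))


@pytest.fixture(scope="session")
def small_null_cohort():
    """A 12-subject no-signal cohort for cheap structural tests."""
    return generate_cohort(compact_config(
        seed=7, n_subjects=12, signal_gain=0.0, global_gain=0.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
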