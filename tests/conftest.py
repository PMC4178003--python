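import numpy as np
import pytest

from sepsipanel import GeneratorConfig, sample_cohort

PANEL = ("Ang-2", "Ang-1", "HCO3")


@pytest.fixture(scope="session")
def default_cohort():
    """Default 45-patient cohort with attrition (seed 42)."""
    return sample_cohort(GeneratorConfig(seed=42))


@pytest.fixture(scope="session")
def dense_cohort():
    """45 patients, no dropout: exactly 450 draws (seed 11)."""
    return sample_cohort(GeneratorConfig(seed=11, dropout_prob=0.0))


@pytest.fixture(scope="session")
def big_cohort():
    """400 patients, no dropout, for Monte-Carlo structure checks."""
    return sample_cohort(GeneratorConfig(seed=5, n_patients=400, dropout_prob=0.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
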