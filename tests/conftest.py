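import numpy as np
import pytest
from hypothesis import settings

from cuetd.models import ModelVariant, SubjectParams

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")
from cuetd.simulate import GroundTruth, simulate_cohort
from cuetd.task import build_design


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def design_set1():
    return build_design(1, 20.0)


@pytest.fixture
def typical_params():
    """A subject near the group-prior means."""
    return SubjectParams(log_k_neut=-4.2, s_ero_k=0.15, beta_neut=0.51,
                         s_ero_beta=0.02, omega_neut=0.8, s_ero_omega=-0.1)


@pytest.fixture
def offset_variant():
    return ModelVariant("offset")


@pytest.fixture
def base_variant():
    return ModelVariant("base")


@pytest.fixture(scope="session")
def small_cohort():
    """8 subjects x 2 conditions, offset-generated; shared across tests."""
    truth_spec = GroundTruth.default(omega_mean=0.7)
    return simulate_cohort(truth_spec, 8, seed=2026)
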