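import numpy as np
import pytest

from scdpk.data_model import AssayConfig, StoppingRule
from scdpk.synthetic import (
    ConcentrationProfile,
    SimConfig,
    SubjectParams,
    clearance_profile,
    simulate_study,
)

#: assay whose LOQ never censors anything (for noise-free identities)
UNCENSORED_ASSAY = AssayConfig(loq_ug_ml=1e-12, lod_ug_ml=1e-15)


@pytest.fixture
def params():
    return SubjectParams()


@pytest.fixture
def uptake4h(params):
    return ConcentrationProfile(params, 4.0)


@pytest.fixture
def clearance6h(uptake4h, params):
    return clearance_profile(uptake4h, 6.0, params.k_true_per_h)


@pytest.fixture
def rule():
    return StoppingRule()


@pytest.fixture
def no_stop_rule():
    return StoppingRule(tewl_abs_max=np.inf, tewl_fold_max=np.inf, max_strips=20)


@pytest.fixture(scope="session")
def small_study():
    """A 3-subject study, shared across tests that only read it."""
    return simulate_study(SimConfig(seed=7, n_subjects=3))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
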