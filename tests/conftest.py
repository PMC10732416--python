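import warnings

import pytest

from gngwm.family import build_model_spec
from gngwm.fitting import MCMCConfig, fit_hierarchical
from gngwm.task import generate_cohort

warnings.filterwarnings("ignore", message=".*ArviZ.*")


@pytest.fixture(scope="session")
def spec1():
    return build_model_spec(1)


@pytest.fixture(scope="session")
def spec8():
    return build_model_spec(8)


@pytest.fixture(scope="session")
def small_cohort(spec8):
    """12-subject cohort from the full model at study-default group values."""
    return generate_cohort(12, None, spec8, None, seed=7)


@pytest.fixture(scope="session")
def tiny_fit(spec1):
    """Small baseline-model fit shared by comparison/summary tests."""
    trials, _ = generate_cohort(6, None, spec1, None, seed=21)
    return trials, fit_hierarchical(
        trials, spec1, MCMCConfig(chains=2, iters=300, warmup=150), seed=21
    )
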