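import numpy as np
import pytest

from thermoresp import MMRTParams, invert_traits
from thermoresp.config import StudyConfig
from thermoresp.pipeline import run_study


@pytest.fixture(scope="session")
def study_seed1():
    """One full default synthetic study, shared across tests."""
    return run_study(StudyConfig(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_mmrt_params(rng: np.random.Generator) -> MMRTParams:
    """Parameter sets with optima in a controlled window, field-like ΔCP‡."""
    topt_k = rng.uniform(285.0, 395.0)
    dcp = rng.uniform(-3400.0, -1100.0)
    r25_val = float(np.exp(rng.uniform(0.0, 4.0)))
    return invert_traits(topt_k, dcp, r25_val)
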