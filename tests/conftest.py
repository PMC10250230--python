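import numpy as np
import pytest
from hypothesis import settings

import autoinhib as ai

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def canonical():
    """Canonical decoy-rich parameter set, K_ai = 50."""
    return ai.canonical_parameters(50.0)


@pytest.fixture(scope="session")
def canonical_reference(canonical):
    return ai.make_uninhibited_reference(canonical)


@pytest.fixture(scope="session")
def canonical_timecourse(canonical):
    return ai.integrate(canonical, t_end=10.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
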