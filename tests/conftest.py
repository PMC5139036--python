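import numpy as np
import pytest

from imvt import FixtureSpec, TwoGroupSample, generate_fixture


@pytest.fixture
def worked_sample():
    """The small worked example used throughout: (1,2,3) vs (2,4,6)."""
    return TwoGroupSample([1, 2, 3], [2, 4, 6], probe_id="worked")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_study():
    """A quick 800-probe study with planted effects and full background."""
    spec = FixtureSpec(n_probes=800, n_planted=12, seed=0)
    study, truth = generate_fixture(spec)
    return study, truth


@pytest.fixture(scope="session")
def standard_fixture():
    """The standard 5000-probe fixture (shared across the expensive tests)."""
    study, truth = generate_fixture(FixtureSpec())
    return study, truth
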