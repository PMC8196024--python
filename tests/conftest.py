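import numpy as np
import pytest

from reciprosim.core import GameParams, Institution, get_norm


@pytest.fixture(scope="session")
def params():
    """Default game parameters used throughout: b=5, c=1, e1=e2=0.02."""
    return GameParams()


@pytest.fixture(scope="session")
def all_norms():
    return [get_norm(n) for n in ("stern_judging", "simple_standing", "scoring", "shunning")]


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def tolerant_q2():
    return Institution.tolerant(2)


@pytest.fixture(scope="session")
def strict_q2():
    return Institution.strict(2)
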