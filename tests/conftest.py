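import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from pmmevol.simulate import make_pmm_fixture  # noqa: E402


@pytest.fixture(scope="session")
def pmm_fixture():
    """The seeded 11-taxon duplicated-family alignment with its true tree."""
    return make_pmm_fixture(seed=1)


@pytest.fixture(scope="session")
def balanced8_tree():
    """Balanced 8-taxon tree used for parameter-recovery simulations."""
    from pmmevol.seqio import parse_newick

    return parse_newick(
        "(((a:0.15,b:0.15):0.1,(c:0.15,d:0.15):0.1):0.05,"
        "((e:0.15,f:0.15):0.1,(g:0.15,h:0.15):0.1):0.05);"
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
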