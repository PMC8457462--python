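import numpy as np
import pytest

from carabclock.timetree import parse_newick


@pytest.fixture
def abc_tree():
    """The worked three-tip example: MRCA(A,B) at 1 Ma, root at 2 Ma."""
    return parse_newick("((A:1.0,B:1.0):1.0,C:2.0);")


@pytest.fixture
def rng():
    return np.random.default_rng(20120)


@pytest.fixture(scope="session")
def nd5_study():
    """The 58-taxon single-marker synthetic study (session-shared)."""
    from carabclock.synthetic_data import make_fixture

    return make_fixture("nd5_extended", seed=58)


def random_time_tree(rng, n_tips):
    """Yule tree helper used by several oracle comparisons."""
    from carabclock.synthetic_data import simulate_yule_tree

    return simulate_yule_tree(n_tips, 1.0, rng)
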