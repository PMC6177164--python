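import numpy as np
import pytest

from altripgls import (SyntheticConfig, load_table, read_newick,
                       simulate_tree, bundled_tree_path)


@pytest.fixture(scope="session")
def study_table():
    return load_table()


@pytest.fixture(scope="session")
def study_tree():
    return read_newick(bundled_tree_path(31))


@pytest.fixture(scope="session")
def study_tree_32():
    return read_newick(bundled_tree_path(32))


@pytest.fixture
def random_tree_factory():
    def make(n_tips=10, seed=0):
        return simulate_tree(SyntheticConfig(n_tips=n_tips, seed=seed))

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(20180)
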