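import numpy as np
import pandas as pd
import pytest

import phylopgls as pg


@pytest.fixture
def three_tip_tree() -> pg.Phylogeny:
    """((A:1,B:1):1,C:2); — A,B share one unit of path, depths all 2."""
    return pg.read_tree("((A:1,B:1):1,C:2);")


@pytest.fixture
def star_tree() -> pg.Phylogeny:
    return pg.read_tree("(A:1,B:1,C:1,D:1,E:1);")


@pytest.fixture(scope="session")
def sixteen_tip_dataset():
    """Default-scenario simulation: 16-tip unit-depth tree + trait table."""
    config = pg.default_scenario(seed=7)
    tree, data = pg.simulate_dataset(config)
    return config, tree, data


@pytest.fixture(scope="session")
def default_spec(sixteen_tip_dataset) -> pg.ModelSpec:
    config, _, _ = sixteen_tip_dataset
    return pg.ModelSpec(config.response, tuple(config.beta_true))


def random_tree(rng: np.random.Generator, n_tips: int) -> pg.Phylogeny:
    """An independent pure-birth draw for oracle comparisons."""
    return pg.simulate_tree(n_tips, seed=int(rng.integers(2**31)))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
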