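import numpy as np
import pytest

from phyloniche.core_io import DatedTree
from phyloniche.synthetic import (default_niche_specs, gen_env_grid,
                                  paper_mimic_dataset)


@pytest.fixture(scope="session")
def small_grid():
    return gen_env_grid(30, seed=11)


@pytest.fixture(scope="session")
def mimic():
    """Paper-mimic synthetic scenario shared across modules (read-only)."""
    return paper_mimic_dataset(3, grid_size=40)


@pytest.fixture(scope="session")
def mimic_specs(mimic):
    return default_niche_specs(mimic["grid"])


@pytest.fixture(scope="session")
def blobs3():
    """Three well-separated Gaussian blobs in 5-D."""
    rng = np.random.default_rng(21)
    centers = np.array([[0.0] * 5, [60.0] * 5, [-60.0, 60.0, -60.0, 60.0, -60.0]])
    X = np.vstack([c + rng.normal(0, 1.0, (40, 5)) for c in centers])
    labels = np.repeat([0, 1, 2], 40)
    return X, labels


@pytest.fixture()
def cherry_tree():
    return DatedTree.from_newick("((a:1,b:1):1,c:2);")
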