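import numpy as np
import pytest

from crowdclust.datagen import generate_subspace_dataset
from crowdclust.puzzle_engine import build_puzzles
from crowdclust.crowd_sim import simulate_solutions


@pytest.fixture(scope="session")
def small_dataset():
    """A 4-feature dataset with three planted subspace clusters + 5% noise."""
    return generate_subspace_dataset(3, 300, 4, 0.05, seed=101)


@pytest.fixture(scope="session")
def small_puzzles(small_dataset):
    return build_puzzles(small_dataset, 10, 60, seed=202)


@pytest.fixture(scope="session")
def faithful_solutions(small_dataset, small_puzzles):
    """A clean, high-fidelity annotator log for the small dataset."""
    return simulate_solutions(small_dataset, small_puzzles, 8,
                              fidelity=1.0, flip_rate=0.0, seed=303)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
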