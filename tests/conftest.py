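import numpy as np
import pandas as pd
import pytest

from phylorpca import Phylogeny, SimulationConfig, parse_newick, simulate


@pytest.fixture
def toy_tree() -> Phylogeny:
    return parse_newick("((A:1,B:2)n1:0.5,C:3)root;")


@pytest.fixture
def toy_table() -> pd.DataFrame:
    return pd.DataFrame(
        [[1, 2, 3], [0, 4, 4], [5, 0, 1]],
        index=["s1", "s2", "s3"],
        columns=["A", "B", "C"],
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Desk-scale block simulation for unit tests (not the benchmark scale)."""
    return SimulationConfig(
        features_per_block=20, samples_per_block=8, depth=50_000, seed=7
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate(small_config)
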