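import numpy as np
import pytest

from indelphy import SimConfig, balanced_tree_newick, paper_fixtures, simulate


@pytest.fixture(scope="session")
def fixtures():
    return paper_fixtures()


@pytest.fixture(scope="session")
def small_sim():
    """One small 8-taxon simulated data set shared across tests."""
    cfg = SimConfig(
        tree=balanced_tree_newick(8, 0.01),
        root_length=20_000,
        indel_rate=0.05,
        seed=42,
    )
    return simulate(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_dna(rng, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))
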