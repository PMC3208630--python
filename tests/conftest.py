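import numpy as np
import pytest

from pamethyl import simulate
from pamethyl.types import BetaMatrix


@pytest.fixture(scope="session")
def small_dataset():
    """12-sample, 300-probe dataset with 30 strongly differential probes."""
    cfg = simulate.SimulationConfig(n_probes=300, n_differential=30, seed=7)
    beta, pheno, truth = simulate.generate_dataset(cfg)
    labels = (pheno["group"] == "PA").to_numpy().astype(int)
    return beta, pheno, truth, labels


@pytest.fixture(scope="session")
def toy_genome():
    """Small genome with planted probes of every validity class."""
    cfg = simulate.SimulationConfig(seed=11)
    return simulate.generate_genome_and_probes(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def beta_2x2():
    return BetaMatrix(
        np.array([[0.1, 0.9], [0.4, 0.6]]), ["s1", "s2"], ["p1", "p2"]
    )
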