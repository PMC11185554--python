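import numpy as np
import pytest

from txpred.core import ExpressionMatrix, standardize_columns
from txpred.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_sparse_dataset():
    """80 lines x 300 genes, 5 causal genes, H2 = 0.8."""
    cfg = SimulationConfig(
        n_lines=80,
        n_genes=300,
        n_blocks=30,
        architecture="sparse",
        n_causal=5,
        heritability=0.8,
        n_terms=20,
        term_size_range=(5, 15),
        seed=7,
    )
    ds, truth = simulate_dataset(cfg)
    return ds, truth, cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_centered(rng, n, m):
    X = rng.standard_normal((n, m))
    X -= X.mean(axis=0)
    y = rng.standard_normal(n)
    y -= y.mean()
    return X, y


@pytest.fixture(scope="session")
def standardized_matrix():
    r = np.random.default_rng(3)
    vals = r.standard_normal((20, 40))
    X = ExpressionMatrix(
        [f"L{i}" for i in range(20)], [f"g{j}" for j in range(40)], vals
    )
    return standardize_columns(X)
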