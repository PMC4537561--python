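import numpy as np
import pandas as pd
import pytest

from acidnet.expression import ExpressionMatrix, TraitTable
from acidnet.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_config():
    """Scaled-down study configuration (5 modules x 30 genes, 100 background)."""
    return SimConfig(module_sizes=(30,) * 5, n_background_genes=100, seed=1)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture()
def tiny_matrix():
    """3 genes x 6 samples, two groups of 3, hand-checkable values."""
    samples = [f"s{i}" for i in range(6)]
    values = pd.DataFrame(
        [
            [1.0, 3.0, 2.0, 4.0, 4.0, 4.0],
            [0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
            [10.0, 12.0, 11.0, 1.0, 2.0, 3.0],
        ],
        index=["g1", "g2", "g3"],
        columns=samples,
    )
    groups = pd.Series(["A", "A", "A", "B", "B", "B"], index=samples)
    return ExpressionMatrix(values, groups)


def random_expression(rng, n_genes=10, n_a=3, n_b=3, scale=5.0):
    samples = [f"a{i}" for i in range(n_a)] + [f"b{i}" for i in range(n_b)]
    values = pd.DataFrame(
        rng.gamma(2.0, scale, size=(n_genes, n_a + n_b)),
        index=[f"g{i}" for i in range(n_genes)],
        columns=samples,
    )
    groups = pd.Series(["A"] * n_a + ["B"] * n_b, index=samples)
    return ExpressionMatrix(values, groups)
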