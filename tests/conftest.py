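import numpy as np
import pandas as pd
import pytest

from coexnet import ExpressionMatrix, generate_expression
from coexnet.synthetic import SyntheticSpec


@pytest.fixture(scope="session")
def default_atlas():
    """Reference synthetic atlas (default study conditions, seed 1)."""
    return generate_expression(SyntheticSpec(), seed=1)


@pytest.fixture(scope="session")
def small_atlas():
    """Small, cheap atlas for I/O and plumbing tests."""
    spec = SyntheticSpec(
        n_genes=200,
        modules=(),
        housekeeping_fraction=0.1,
        library_depth=100_000,
    )
    return generate_expression(spec, seed=7)


def random_matrix(rng, n_genes=30, n_samples=10, unit="TPM"):
    vals = rng.gamma(shape=1.0, scale=50.0, size=(n_genes, n_samples))
    return ExpressionMatrix(
        pd.DataFrame(vals,
                     index=[f"g{i:03d}" for i in range(n_genes)],
                     columns=[f"s{j:02d}" for j in range(n_samples)]),
        unit=unit)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
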