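import numpy as np
import pytest

from scdrp.expression import ExpressionMatrix
from scdrp.synthetic import SyntheticConfig, generate


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def tiny_counts():
    """A small raw bulk count matrix with known structure."""
    rng = np.random.default_rng(1)
    values = rng.poisson(5.0, size=(6, 8)).astype(float)
    values[0, 0] = 10.0  # ensure nonzero
    return ExpressionMatrix(
        values=values,
        gene_names=[f"g{j}" for j in range(8)],
        sample_ids=[f"s{i}" for i in range(6)],
        domain="bulk",
    )


@pytest.fixture(scope="session")
def small_dataset():
    """A scaled-down synthetic dataset shared across training tests."""
    cfg = SyntheticConfig(
        seed=7,
        n_genes=120,
        n_pathways=8,
        genes_per_pathway=(6, 10),
        n_bulk=80,
        n_sc=150,
        causal_pathways=(0, 1),
    )
    return generate(cfg)
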