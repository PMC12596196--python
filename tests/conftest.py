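import numpy as np
import pandas as pd
import pytest

import modulome as m
from modulome.expression import ExpressionMatrix


@pytest.fixture(scope="session")
def small_dataset():
    """5 planted modules in a 600-gene, 60-sample compendium."""
    return m.generate(
        n_genes=600, n_samples=60, k_modules=5, module_size_range=(8, 15), seed=3
    )


@pytest.fixture(scope="session")
def small_decomposition(small_dataset):
    xc = small_dataset.centered()
    runs = m.run_ensemble(xc, 5, n_runs=8)
    return m.cluster_components(runs, xc, min_cluster_size=4), xc


def centered_matrix(values, gene_ids=None, sample_ids=None) -> ExpressionMatrix:
    """Wrap an array as an already-centered expression matrix (may be negative)."""
    values = np.asarray(values, dtype=float)
    genes = gene_ids or [f"g{i}" for i in range(values.shape[0])]
    samples = sample_ids or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples), is_centered=True
    )
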