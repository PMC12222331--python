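import numpy as np
import pytest

from icasig.io import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_counts():
    """A tiny 4-gene x 3-sample raw count matrix."""
    return ExpressionMatrix(
        values=np.array(
            [
                [10.0, 20.0, 5.0],
                [0.0, 4.0, 1.0],
                [30.0, 60.0, 15.0],
                [1.0, 2.0, 0.0],
            ]
        ),
        gene_ids=("ACTB", "GAPDH", "TP53", "MYC"),
        sample_ids=("s1", "s2", "s3"),
    )


def gaussian_matrix(seed, genes=2000, samples=60):
    """Pure i.i.d. Gaussian noise shifted non-negative (no planted structure)."""
    r = np.random.default_rng(seed)
    return ExpressionMatrix(
        values=r.standard_normal((genes, samples)) + 10.0,
        gene_ids=tuple(f"g{i}" for i in range(genes)),
        sample_ids=tuple(f"s{j}" for j in range(samples)),
        normalized_flag="external",
    )
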