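"""Shared fixtures: small simulated datasets reused across test modules."""

import numpy as np
import pytest
import scipy.sparse as sp

from denorm import (
    DeltaParams,
    GeneExpressionMatrix,
    delta_normalize,
    simulate_counts,
)


@pytest.fixture(scope="session")
def counts_300():
    """Droplet-like NB counts, 300 cells x 1500 genes, default conditions."""
    return simulate_counts(300, 1500, seed=2)


@pytest.fixture(scope="session")
def normalized_300(counts_300):
    """The log1p / CPM-1e4 image of ``counts_300``."""
    return delta_normalize(counts_300, DeltaParams())


@pytest.fixture()
def tiny_counts():
    """A hand-sized integer matrix with a clean count ladder in every cell."""
    rng = np.random.default_rng(42)
    X = rng.negative_binomial(3, 0.6, size=(20, 60)).astype(float)
    X[:, 0] += 1  # ensure no zero library sizes
    return GeneExpressionMatrix(sp.csr_matrix(X), stage="counts")


def cell_from_tallies(tallies):
    """Build a 1-cell matrix whose stored values follow (value, freq) pairs."""
    data = np.concatenate([[v] * f for v, f in tallies]).astype(float)
    X = sp.csr_matrix(data[None, :])
    return X.data.copy(), X
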