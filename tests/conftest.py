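import numpy as np
import pytest
import scipy.sparse as sp

from meiohic.matrixio import BinTable, ContactMap


def make_random_map(n_bins: int, seed: int = 0, bin_size: int = 10_000,
                    n_chroms: int = 1, density: float = 1.0,
                    unit_weights: bool = True) -> ContactMap:
    """Dense-ish random symmetric map with positive counts, unit weights."""
    rng = np.random.default_rng(seed)
    per = n_bins // n_chroms
    bt = BinTable(tuple((f"chr{i+1}", per * bin_size) for i in range(n_chroms)),
                  bin_size)
    n = bt.n_bins
    upper = np.triu(rng.poisson(5.0, size=(n, n)).astype(float))
    if density < 1.0:
        upper *= rng.random((n, n)) < density
    counts = sp.csr_matrix(upper)
    weights = np.ones(n) if unit_weights else None
    return ContactMap(bt, counts, weights)


def dense_symmetric(cmap: ContactMap, balanced: bool = True) -> np.ndarray:
    """Reference dense symmetric matrix built the straightforward way."""
    a = cmap.counts.toarray()
    full = a + np.triu(a, k=1).T
    if balanced:
        w = cmap.weights
        full = full * np.outer(w, w)
    return full


@pytest.fixture
def random_map():
    return make_random_map


@pytest.fixture
def dense_of():
    return dense_symmetric
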