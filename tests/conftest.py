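import numpy as np
import pytest

from brvd import Dataset, PriorConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_data(rng):
    """20 subjects x 3 variants, no covariates (oracle-enumerable)."""
    n, P = 20, 3
    G = rng.integers(0, 3, size=(n, P)).astype(float)
    freq = G.mean(axis=0) / 2.0
    G[:, freq > 0.5] = 2.0 - G[:, freq > 0.5]
    y = rng.integers(0, 2, n)
    return Dataset(y=y, G=G)


@pytest.fixture
def small_data(rng):
    """60 subjects x 8 variants with one covariate column."""
    n, P = 60, 8
    G = (rng.random((n, P)) < 0.08).astype(float)
    G += (rng.random((n, P)) < 0.05)
    G = np.minimum(G, 2.0)
    # guarantee polymorphism
    for j in range(P):
        if G[:, j].sum() == 0:
            G[j % n, j] = 1.0
    Z = rng.normal(size=(n, 1))
    y = rng.integers(0, 2, n)
    return Dataset(y=y, G=G, Z=Z)


@pytest.fixture
def toy_cfg():
    """Narrow variance prior used by the grid-mode toys."""
    return PriorConfig(gammaL=0.5, gammaU=0.9, l=0.5, u=2.0)
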