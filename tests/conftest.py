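import numpy as np
import pytest

from ddigip import (
    DdigipParams,
    DrugIndex,
    FeatureMatrix,
    InteractionMatrix,
    SynthConfig,
    generate,
)


@pytest.fixture
def two_drug_network():
    """The smallest interacting network: one edge between two drugs."""
    idx = DrugIndex.from_ids(["A", "B"])
    return InteractionMatrix(np.array([[0.0, 1.0], [1.0, 0.0]]), idx)


@pytest.fixture
def path_network():
    """Three drugs, single edge (0,1); drug 2 has no interactions."""
    idx = DrugIndex.from_ids(["A", "B", "C"])
    y = np.zeros((3, 3))
    y[0, 1] = y[1, 0] = 1.0
    return InteractionMatrix(y, idx)


def random_interactions(rng, n, p=0.3):
    """Random symmetric binary matrix with at least one edge."""
    upper = np.triu(rng.random((n, n)) < p, k=1)
    y = (upper | upper.T).astype(float)
    if not y.any():
        y[0, 1] = y[1, 0] = 1.0
    ids = DrugIndex.from_ids(f"d{i:03d}" for i in range(n))
    return InteractionMatrix(y, ids)


def random_psd_kernel(rng, n):
    """Random PSD kernel with unit diagonal (Gaussian kernel of random points)."""
    x = rng.normal(size=(n, 3))
    d2 = ((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2)
    g = np.exp(-d2 / max(d2.mean(), 1e-9))
    np.fill_diagonal(g, 1.0)
    return g


@pytest.fixture(scope="session")
def synth_default():
    """One default-config synthetic dataset shared across tests."""
    return generate(SynthConfig(seed=11))


@pytest.fixture
def default_params():
    return DdigipParams()
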