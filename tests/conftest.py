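import numpy as np
import pytest

from dnmfdda import DatasetBundle, Hyperparams, LabeledMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def light_params():
    """Cheap optimizer settings for protocol plumbing tests."""
    return Hyperparams(taus=(0.5,), max_iter=10, pretrain_iters=30, seed=7)


def make_similarity(rng, n):
    s = rng.uniform(size=(n, n))
    s = (s + s.T) / 2
    np.fill_diagonal(s, 1.0)
    return s


@pytest.fixture
def tiny_bundle(rng):
    """Hand-sized bundle: 8 drugs x 6 diseases, one similarity per side."""
    m, n = 8, 6
    A = np.zeros((m, n))
    A[[0, 1, 2, 3, 4, 5, 6], [0, 1, 2, 3, 4, 5, 0]] = 1
    A[0, 3] = 1  # drug 0 has two positives; drugs 1-6 are singletons; drug 7 empty
    drugs = [f"R{i}" for i in range(m)]
    diseases = [f"D{j}" for j in range(n)]
    return DatasetBundle(
        LabeledMatrix(A, drugs, diseases),
        {"sim": LabeledMatrix(make_similarity(rng, m), drugs, drugs)},
        {"sim": LabeledMatrix(make_similarity(rng, n), diseases, diseases)},
    )
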