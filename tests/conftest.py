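import numpy as np
import pytest

from cgsda.data import AssociationDataset
from cgsda.synthetic import SyntheticConfig, generate_planted_bipartite


@pytest.fixture
def tiny_dataset():
    """2 snoRNAs x 2 diseases with edges (s1,d1), (s2,d1), (s2,d2)."""
    return AssociationDataset(
        snorna_ids=["s1", "s2"],
        disease_ids=["d1", "d2"],
        A=np.array([[1, 0], [1, 1]]),
    )


@pytest.fixture(scope="session")
def small_planted():
    """A small planted fixture cheap enough for training tests."""
    cfg = SyntheticConfig(n_s=60, n_d=15, rank=4, density=0.06,
                          feature_dim=16, seed=1)
    dataset, F_s, F_d, truth = generate_planted_bipartite(cfg)
    return dataset, F_s, F_d, truth


def random_bipartite_Y(rng, n_s, n_d, p=0.3):
    """Random symmetric block adjacency for spectral tests."""
    A = (rng.random((n_s, n_d)) < p).astype(float)
    n = n_s + n_d
    Y = np.zeros((n, n))
    Y[:n_s, n_s:] = A
    Y[n_s:, :n_s] = A.T
    return Y
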