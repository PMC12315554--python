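import numpy as np
import pytest

from convntc import (SimilarityMatrix, SyntheticSpec, TripletDataset,
                     gen_planted)
from convntc.data_model import IncompleteTensor
from convntc.mctd import reconstruct_cp
from convntc.synthetic import _factor_similarity


@pytest.fixture(scope="session")
def planted_default():
    """The default planted study conditions shared across end-to-end tests."""
    return gen_planted(SyntheticSpec())


@pytest.fixture(scope="session")
def noiseless_rank2():
    """Continuous noiseless rank-2 symmetric tensor, 30% of cells observed."""
    rng = np.random.default_rng(3)
    n_A, n_B, r = 20, 10, 2
    M = rng.uniform(size=(n_A, r))
    D = rng.uniform(size=(n_B, r))
    T = reconstruct_cp(M, M, D)
    entries = {}
    for i in range(n_A):
        for j in range(i, n_A):
            for k in range(n_B):
                if rng.uniform() < 0.3:
                    entries[(i, j, k)] = T[i, j, k]
                    entries[(j, i, k)] = T[i, j, k]
    X = IncompleteTensor((n_A, n_A, n_B), entries)
    Sm = _factor_similarity(M, 0.0, rng)
    Sd = _factor_similarity(D, 0.0, rng)
    return X, Sm, Sd, (M, D)


def random_similarity(rng, n: int) -> SimilarityMatrix:
    A = rng.uniform(size=(n, n))
    return SimilarityMatrix(0.5 * (A + A.T))


@pytest.fixture
def tiny_dataset():
    return TripletDataset(
        [(0, 1, 0), (0, 2, 1), (1, 2, 0), (0, 0, 1)],
        np.array([1, 1, 0, 1]), n_A=3, n_B=2)
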