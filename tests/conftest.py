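import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from connectogene import AssociationMatrix, SyntheticSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def barbell():
    """Two unit-weight triangles {a,b,c} and {d,e,f} joined by the bridge c-d."""
    A = np.zeros((6, 6))
    for i, j in [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5), (2, 3)]:
        A[i, j] = A[j, i] = 1.0
    return AssociationMatrix(A, list("abcdef"))


def random_preprocessed(n, rng, density=0.4):
    """Random symmetric nonnegative matrix scaled to [0, 1], zero diagonal."""
    W = rng.random((n, n)) * (rng.random((n, n)) < density)
    W = np.triu(W, k=1)
    W = W + W.T
    if W.max() <= 0:  # pathological draw; re-densify
        W[0, 1] = W[1, 0] = 1.0
    W = W / W.max()
    hit = np.unravel_index(np.argmax(np.triu(W, 1)), W.shape)
    W[hit] = W[hit[::-1]] = 1.0
    return AssociationMatrix(W)


@pytest.fixture
def small_spec():
    return SyntheticSpec(n_subjects=20, n_nodes=40, n_modules=2, n_timepoints=60,
                         n_genes=300, n_planted=20, seed=11)
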