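import numpy as np
import pytest

from sparseped.pedigree import Pedigree


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def pedigree_from_arrays(father, mother):
    n = len(father)
    ids = np.array([f"P{i}" for i in range(n)], dtype=object)
    return Pedigree(
        ids=ids,
        father=np.asarray(father, dtype=np.int64),
        mother=np.asarray(mother, dtype=np.int64),
    )


@pytest.fixture
def trio():
    """Two unrelated founders and their child."""
    return pedigree_from_arrays([-1, -1, 0], [-1, -1, 1])


@pytest.fixture
def sib_family():
    """Founders 0, 1, 2; full sibs 3 and 4 (parents 0 x 1); individual 5
    is a half-sib of them through the shared father 0 (mother 2)."""
    return pedigree_from_arrays(
        [-1, -1, -1, 0, 0, 0], [-1, -1, -1, 1, 1, 2]
    )


@pytest.fixture
def inbred_family():
    """Full sibs mated: their child is inbred with f = 1/4."""
    return pedigree_from_arrays(
        [-1, -1, 0, 0, 2], [-1, -1, 1, 1, 3]
    )
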