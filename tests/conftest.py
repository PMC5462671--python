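import numpy as np
import pytest

import algomd as am


@pytest.fixture(scope="session")
def isonicotinic():
    return am.generate_fixtures("isonicotinic_acid")[0]


@pytest.fixture(scope="session")
def fixture_set():
    return am.generate_fixtures("all")


@pytest.fixture(scope="session")
def random_set():
    return am.random_molecules(30, seed=7)


def walk_count_oracle(M: np.ndarray, k: int) -> np.ndarray:
    """Brute-force walk counts: sum over all vertex sequences of the
    product of pseudograph multiplicities along the sequence."""
    import itertools

    n = M.shape[0]
    out = np.zeros((n, n), dtype=object)
    if k == 0:
        return np.eye(n, dtype=object)
    for i in range(n):
        for j in range(n):
            total = 0
            for mids in itertools.product(range(n), repeat=k - 1):
                seq = (i, *mids, j)
                prod = 1
                for a, b in zip(seq, seq[1:]):
                    prod *= int(M[a, b])
                    if prod == 0:
                        break
                total += prod
            out[i, j] = total
    return out


def naive_lovei(M: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """O(n^3) reference: per row a, build the row-restricted matrix and take
    the full double sum."""
    n = M.shape[0]
    out = np.zeros(n)
    for a in range(n):
        Ma = np.zeros_like(M)
        Ma[a, :] = M[a, :]
        acc = 0.0
        for i in range(n):
            for j in range(n):
                acc += x[i] * Ma[i, j] * y[j]
        out[a] = acc
    return out
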