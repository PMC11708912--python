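import numpy as np
import pytest

from mdsd.networks import make_star_network, sample_gaussian


@pytest.fixture(scope="session")
def small_star_data():
    """p=60 two-star network with n=80 Gaussian samples (fast regime)."""
    truth = make_star_network(60, 2)
    data = sample_gaussian(truth, 80, seed=123)
    return truth, data


def brute_force_mdsd(degrees):
    """Literal double-sum definition of MDSD; the independent oracle.

    MDSD_i = 1/(M(p-1)) * sum over models and over j != i of
    (d_i - d_j)^2, computed with explicit loops.
    """
    D = np.asarray(degrees, dtype=float)
    p, M = D.shape
    out = np.zeros(p)
    for i in range(p):
        total = 0.0
        for m in range(M):
            for j in range(p):
                if j != i:
                    total += (D[i, m] - D[j, m]) ** 2
        out[i] = total / (M * (p - 1))
    return out
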