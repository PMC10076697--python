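import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from leascore import WordList

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def wl() -> WordList:
    """A small hand-built German emotion wordlist with a phrase entry."""
    return WordList.from_pairs(
        [
            ("traurig", 3),
            ("wütend", 3),
            ("enttäuscht", 3),
            ("ängstlich", 3),
            ("weinen", 2),
            ("schlecht", 2),
            ("kopfschmerzen", 1),
            ("herzrasen", 1),
            ("sehr traurig", 3),
        ]
    )


@pytest.fixture
def exact_correlation_data():
    """Three vectors with exact sample correlations r_xy=0.6, r_xz=0.5, r_yz=0.5.

    Built from an exactly orthonormal mean-zero basis (iterated QR), then
    colored with the Cholesky factor of the target correlation matrix, so the
    closed-form first-order partial correlation (0.6 - 0.25)/0.75 = 7/15 is
    an exact expectation rather than an approximation.
    """
    n = 12
    rng = np.random.default_rng(0)
    A = rng.normal(size=(n, 3))
    A -= A.mean(axis=0)
    Q, _ = np.linalg.qr(A)
    for _ in range(3):
        Q -= Q.mean(axis=0)
        Q, _ = np.linalg.qr(Q)
    C = np.array([[1.0, 0.6, 0.5], [0.6, 1.0, 0.5], [0.5, 0.5, 1.0]])
    X = Q @ np.linalg.cholesky(C).T
    return X[:, 0], X[:, 1], X[:, 2]
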