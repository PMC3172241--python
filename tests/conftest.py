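import numpy as np
import pytest

from cpascene.dictionary import Dictionary


def orthogonal_zero_mean_dictionary(n: int, f: int, seed: int = 0) -> Dictionary:
    """n mutually orthogonal, zero-mean, unit-norm elements of length f.

    QR on a column-zero-mean random matrix: the orthonormal columns stay in
    the zero-sum hyperplane, so they are valid dictionary elements.
    """
    assert n < f, "need n < f for an orthogonal zero-mean set"
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((f, n))
    X -= X.mean(axis=0, keepdims=True)
    Q, _ = np.linalg.qr(X)
    return Dictionary(Q.T[:n])


@pytest.fixture
def ortho_dict():
    return orthogonal_zero_mean_dictionary(4, 12, seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
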