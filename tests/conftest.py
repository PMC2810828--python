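import numpy as np
import pytest

import splsreg as s


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def uni_data(rng):
    """Univariate-response regression with grouped signal, n > p."""
    X = rng.standard_normal((30, 8))
    y = X[:, :3] @ np.array([2.0, -1.0, 1.5]) + 0.4 * rng.standard_normal(30)
    return s.center_scale(X, y[:, None])


@pytest.fixture
def multi_data(rng):
    """Three-response regression driven by a rank-two coefficient matrix."""
    X = rng.standard_normal((40, 10))
    B = np.zeros((10, 3))
    B[:4, 0] = [1.5, -2.0, 1.0, 0.5]
    B[2:6, 1] = [1.0, 1.0, -1.5, 2.0]
    B[:, 2] = 0.5 * B[:, 0] - B[:, 1]
    Y = X @ B + 0.3 * rng.standard_normal((40, 3))
    return s.center_scale(X, Y)
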