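import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_dataset(rng):
    """Two well-separated clusters with disjoint label sets, fully labeled."""
    n_half, d = 15, 4
    X = np.vstack(
        [
            rng.normal(loc=0.0, scale=0.3, size=(n_half, d)),
            rng.normal(loc=5.0, scale=0.3, size=(n_half, d)),
        ]
    )
    Y = np.full((2 * n_half, 3), -1, dtype=np.int8)
    Y[:n_half, 0] = 1
    Y[n_half:, 1] = 1
    Y[n_half:, 2] = 1
    return X, Y
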