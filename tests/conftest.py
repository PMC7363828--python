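import numpy as np
import pytest

from osscca.data import impute_and_standardize


def standardized_instance(seed: int, n: int = 30, p: int = 4, q: int = 3, signal: float = 0.0):
    """Random column-standardized (X, Y, z) triplet; ``signal`` mixes a shared
    latent factor into all three blocks."""
    rng = np.random.default_rng(seed)
    latent = rng.standard_normal(n)
    X = rng.standard_normal((n, p)) + signal * latent[:, None]
    Y = rng.standard_normal((n, q)) + signal * latent[:, None]
    z_raw = rng.standard_normal(n) + signal * latent
    Xs, _ = impute_and_standardize(X)
    Ys, _ = impute_and_standardize(Y)
    Zs, _ = impute_and_standardize(z_raw)
    return Xs, Ys, Zs[:, 0]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
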