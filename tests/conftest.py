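import numpy as np
import pytest

from rmtcpt import TimeSeriesMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def gaussian_series():
    """Factory for IID Gaussian d x T series (optionally with a covariance
    jump after tau)."""

    def make(d=5, T=200, seed=0, sigma=None, sigma_post=None, tau=None):
        gen = np.random.default_rng(seed)
        if sigma is None:
            sigma = np.eye(d)
        chol = np.linalg.cholesky(sigma)
        y = chol @ gen.standard_normal((d, T))
        if sigma_post is not None:
            chol2 = np.linalg.cholesky(sigma_post)
            y[:, tau:] = chol2 @ gen.standard_normal((d, T - tau))
        return TimeSeriesMatrix(y)

    return make
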