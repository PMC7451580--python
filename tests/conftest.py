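import numpy as np
import pytest

from tiht import TIHTWParams, tihtw_quantile, weibull_baseline, WeibullParams


@pytest.fixture(scope="session")
def heavy_params():
    """A heavy-tailed (theta < 1) TI-HT-Weibull parameter point."""
    return TIHTWParams(alpha=0.8, gamma=1.0, theta=0.5)


@pytest.fixture(scope="session")
def mild_params():
    return TIHTWParams(alpha=1.4, gamma=1.0, theta=0.9)


@pytest.fixture(scope="session")
def weibull_base():
    return weibull_baseline(WeibullParams(alpha=1.2, gamma=0.7))


def make_sample(params: TIHTWParams, n: int, seed: int) -> np.ndarray:
    """Inversion sample used across tests (deterministic)."""
    u = np.random.default_rng(seed).random(n)
    return np.asarray(tihtw_quantile(u, params))


@pytest.fixture(scope="session")
def sample_5000(heavy_params):
    return make_sample(heavy_params, 5000, seed=1)
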