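import numpy as np
import pytest

from hmmindy import _kernels
from hmmindy.model import ModelParams, ObservationModel
from hmmindy.synth import SynthSpec, generate_dataset


@pytest.fixture(scope="session", autouse=True)
def _warm_kernels():
    """Compile the numba kernels once, up front."""
    _kernels.warmup()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def tiny_params(n_exc=3, m=2, seed=0):
    """Small hand-sized model with full (unmasked) structure."""
    rng = np.random.default_rng(seed)
    n = 2 * n_exc
    W = np.zeros((n, n))
    W[:, :n_exc] = 0.3 * rng.random((n, n_exc))
    W[:n_exc, n_exc:] = -np.diag(0.3 * rng.random(n_exc))
    W[n_exc:, n_exc:] = -np.diag(0.3 * rng.random(n_exc))
    g = 1.0 + 0.1 * rng.standard_normal((m, n))
    D = np.concatenate([np.full(n_exc, 0.7), np.full(n_exc, 0.8)])
    S = np.concatenate([np.full(n_exc, 2.5), np.full(n_exc, 1.0)])
    return ModelParams(n_exc, n_exc, W, np.abs(g), D, S,
                       np.zeros(n), np.zeros(n))


def tiny_obs(n_exc=3, seed=0, q=0.25, r=0.3):
    rng = np.random.default_rng(seed)
    H = np.hstack([rng.standard_normal((n_exc, n_exc)),
                   np.zeros((n_exc, n_exc))])
    return ObservationModel(H, q * np.eye(2 * n_exc), r * np.eye(n_exc))


@pytest.fixture()
def small_model():
    return tiny_params()


@pytest.fixture()
def small_obs():
    return tiny_obs()


@pytest.fixture(scope="session")
def small_dataset():
    """A small but dynamically realistic synthetic recording."""
    return generate_dataset(SynthSpec(n_exc=4, T=600), seed=7)
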