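"""Ground-truth synthetic data generator.

Creates random constrained excitatory/inhibitory models and simulates
regime-switching multichannel recordings from them, for validating the
blind-identification pipeline against known parameters.

The connectivity submatrices combine a low-rank "backbone" with a sparse
component,

    Wee = Ws + W_l1 W_l2^T + diag(w_diag),

with entry laws: sparse part ``0.8 U(0,1)^3`` per entry, low-rank factor
entries ``U(0,1)^3 + 0.2 U(0,1)`` (factors are n x n/4), and the same
construction for Wei.  A random structural mask then zeroes 75% of each
block's off-diagonal entries; Wie and Wii are diagonal.  Modulation
vectors are drawn either independently per regime (uniform or normal
family, mean ~ N(1, 0.1)) or jointly from a multivariate normal whose
off-diagonal cross-covariance rho controls how similar the regimes are.
Regime labels come from a near-diagonal Markov chain (stay probability
0.9995), giving a slow switching process relative to the millisecond-scale
neural dynamics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .hmm import HmmParams, near_diagonal_transitions, uniform_initial, \
    simulate_states
from .model import ModelParams, ObservationModel, make_mask, simulate

__all__ = ["SynthSpec", "SynthDataset", "make_connectivity",
           "make_modulations", "make_ground_truth", "generate_dataset"]

log = logging.getLogger("hmmindy")


@dataclass
class SynthSpec:
    """Study conditions for the generator.

    rho=None selects the independent per-regime modulation mode (uniform /
    normal mixture); a float selects the correlated multivariate-normal
    mode with that cross-covariance.
    """

    n_exc: int = 16
    m: int = 2
    T: int = 20000
    rho: float | None = None
    # nonlinearity and decay
    s_exc: float = 2.5
    s_inh: float = 1.0
    d_exc_base: float = 0.65
    d_inh_base: float = 0.8
    d_jitter: float = 0.02
    # noise scales: Q on the state (process), R on the channels (measurement)
    q_scale: float = 0.25
    r_base: float = 0.2
    r_jitter: float = 0.1
    # connectivity entry laws
    ws_scale: float = 0.8
    lowrank_lin: float = 0.2
    mask_keep: float = 0.25
    ei_balance: tuple = (0.9, 1.1)   # Wie/Wii diag as multiple of row input
    # modulation vector laws
    mu_mean: float = 1.0
    mu_sd: float = 0.1
    sigma_uniform: tuple = (0.4, 0.1)
    sigma_normal: tuple = (0.05, 0.01)
    # switching chain
    stay_prob: float = 0.9995
    # stability rejection
    max_resample: int = 20
    stability_check_T: int = 1000

    def validate(self) -> None:
        if self.n_exc < 4:
            raise ValueError("n_exc must be >= 4 (low-rank factors are n x n/4)")
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if self.m < 1:
            raise ValueError("m must be >= 1")


@dataclass
class SynthDataset:
    """A simulated recording plus everything needed for recovery scoring."""

    Y: np.ndarray                # (c, T) observations
    labels: np.ndarray           # (T,) true regime labels
    states: np.ndarray           # (n, T) true neural trajectory
    params: ModelParams
    obs: ObservationModel
    hmm: HmmParams
    seed: int


def _cube_uniform(rng, shape):
    return rng.random(shape) ** 3


def make_connectivity(spec: SynthSpec, seed=None, rng=None):
    """Draw the four connectivity blocks (magnitudes) and the mask.

    Returns (Wee, Wei, Wie_diag, Wii_diag, mask); Wee/Wei already have the
    75% off-diagonal mask applied.
    """
    spec.validate()
    if rng is None:
        rng = np.random.default_rng(seed)
    n = spec.n_exc
    k = n // 4
    mask = make_mask(n, n, rng, density=spec.mask_keep)

    def block():
        sparse = spec.ws_scale * _cube_uniform(rng, (n, n))
        l1 = _cube_uniform(rng, (n, k)) + spec.lowrank_lin * rng.random((n, k))
        l2 = _cube_uniform(rng, (n, k)) + spec.lowrank_lin * rng.random((n, k))
        w = sparse + l1 @ l2.T + np.diag(_cube_uniform(rng, n))
        return w

    Wee = block() * mask[:n]
    Wei = block() * mask[n:]
    # inhibitory diagonals are drawn to balance the excitatory input each
    # population receives (E/I balance): without comparable inhibition the
    # network sits in deep tanh saturation and behaves as a quasi-binary
    # attractor system rather than a fluctuating neural population model
    lo, hi = spec.ei_balance
    Wie = rng.uniform(lo, hi, n) * Wee.sum(axis=1)
    Wii = rng.uniform(lo, hi, n) * Wei.sum(axis=1)
    return Wee, Wei, Wie, Wii, mask


def _psd_bound(sigmas: np.ndarray) -> float:
    """Largest admissible equal off-diagonal cross-covariance for the given
    diagonal variances (sufficient bound: min pairwise sqrt(s_i s_j))."""
    m = sigmas.shape[0]
    if m < 2:
        return np.inf
    s = np.sort(sigmas)
    return float(np.sqrt(s[0] * s[1]))


def make_modulations(spec: SynthSpec, seed=None, rng=None):
    """Draw the m rank-1 modulation matrices and their generating vectors.

    Independent mode (rho=None): per regime, mean mu_i ~ N(1, 0.1); a fair
    coin picks the family; uniform uses width sigma_i ~ N(0.4, 0.1) with
    g ~ U(mu - sigma/2, mu + sigma/2), normal uses variance
    sigma_i ~ N(0.05, 0.01) with g ~ N(mu, sigma).

    Correlated mode: for each population, the m-vector of regime values is
    drawn from N(mu, Sigma) with Sigma = diag(sigma_i) + rho off-diagonal.

    Returns (Gamma (m, n, n), g (m, n)).
    """
    spec.validate()
    if rng is None:
        rng = np.random.default_rng(seed)
    n2 = 2 * spec.n_exc
    m = spec.m
    mus = spec.mu_mean + spec.mu_sd * rng.standard_normal(m)
    if spec.rho is None:
        g = np.empty((m, n2))
        for i in range(m):
            if rng.random() < 0.5:   # uniform family
                width = rng.normal(*spec.sigma_uniform)
                width = abs(width)
                g[i] = rng.uniform(mus[i] - 0.5 * width,
                                   mus[i] + 0.5 * width, size=n2)
            else:                    # normal family, sigma is a variance
                var = abs(rng.normal(*spec.sigma_normal))
                g[i] = rng.normal(mus[i], np.sqrt(var), size=n2)
    else:
        sig = np.abs(spec.sigma_normal[0]
                     + spec.sigma_normal[1] * rng.standard_normal(m))
        bound = _psd_bound(sig)
        Sigma = np.full((m, m), float(spec.rho))
        np.fill_diagonal(Sigma, sig)
        if np.min(np.linalg.eigvalsh(Sigma)) < 0:
            raise ValueError(
                f"rho={spec.rho} makes Sigma indefinite; need |rho| <= "
                f"~{bound:.4f} for these variances")
        L = np.linalg.cholesky(Sigma + 1e-12 * np.eye(m))
        g = (mus[:, None] + L @ rng.standard_normal((m, n2)))
    g = np.clip(g, 0.0, None)
    Gamma = np.einsum("ki,kj->kij", g, g)
    return Gamma, g


def make_ground_truth(spec: SynthSpec, seed=None, rng=None):
    """Assemble a full generative model: constrained connectivity,
    modulations, observation model and switching chain.

    Models whose noise-free dynamics diverge in a short probe simulation
    are resampled (with a logged count); with retention below one this is
    rare by construction.
    """
    spec.validate()
    if rng is None:
        rng = np.random.default_rng(seed)
    n_exc = spec.n_exc
    n = 2 * n_exc

    for attempt in range(spec.max_resample):
        Wee, Wei, Wie, Wii, mask = make_connectivity(spec, rng=rng)
        Gamma, g = make_modulations(spec, rng=rng)
        W = np.zeros((n, n))
        W[:n_exc, :n_exc] = Wee
        W[n_exc:, :n_exc] = Wei
        W[:n_exc, n_exc:] = -np.diag(Wie)
        W[n_exc:, n_exc:] = -np.diag(Wii)
        D = np.concatenate([
            np.full(n_exc, spec.d_exc_base + spec.d_jitter * rng.random()),
            np.full(n_exc, spec.d_inh_base + spec.d_jitter * rng.random())])
        S = np.concatenate([np.full(n_exc, spec.s_exc),
                            np.full(n_exc, spec.s_inh)])
        params = ModelParams(n_exc, n_exc, W, g, D, S,
                             np.zeros(n), np.zeros(n), mask)

        Hexc = rng.standard_normal((n_exc, n_exc))
        H = np.hstack([Hexc, np.zeros((n_exc, n_exc))])
        Q = spec.q_scale * np.eye(n)
        R = (spec.r_base + spec.r_jitter * rng.random()) * np.eye(n_exc)
        obs = ObservationModel(H, Q, R)
        hmm = HmmParams(near_diagonal_transitions(spec.m, spec.stay_prob),
                        uniform_initial(spec.m))

        if _is_stable(params, spec, rng):
            if attempt:
                log.info("resampled %d unstable model draw(s)", attempt)
            params.validate()
            obs.validate()
            return params, obs, hmm
    raise RuntimeError("could not draw a stable model within max_resample tries")


def _is_stable(params: ModelParams, spec: SynthSpec,
               rng: np.random.Generator) -> bool:
    x = rng.standard_normal(params.n)
    Wg = params.modulated_W()
    for t in range(spec.stability_check_T):
        x = Wg[t % params.m] @ np.tanh(params.S * x + params.V) \
            + params.D * x + params.C
        if not np.all(np.isfinite(x)) or np.max(np.abs(x)) > 1e6:
            return False
    return True


def generate_dataset(spec: SynthSpec, seed: int = 0) -> SynthDataset:
    """Draw a ground-truth model, simulate its switching chain and forward
    simulate the recording.  Bit-reproducible for a given (spec, seed)."""
    rng = np.random.default_rng(seed)
    params, obs, hmm = make_ground_truth(spec, rng=rng)
    labels = simulate_states(hmm, spec.T, rng=rng)
    states, Y = simulate(params, obs, labels, rng=rng)
    return SynthDataset(Y=Y, labels=labels, states=states, params=params,
                        obs=obs, hmm=hmm, seed=seed)
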