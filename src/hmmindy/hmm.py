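"""Hidden Markov machinery over dynamical regimes.

Conventions
-----------
The transition matrix ``A`` is *column*-stochastic: ``A[i, j]`` is the
probability of moving to regime ``i`` given the current regime ``j``, so
state-probability columns propagate as ``p_{t+1} = A p_t``.  Emission
likelihoods are unnormalized nonnegative weights (here, inverted Kalman
residuals); forward-backward rescales at every step, so only their ratios
within a timepoint matter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["HmmParams", "RegimePosterior", "ForwardBackwardResult",
           "near_diagonal_transitions", "uniform_initial", "simulate_states",
           "forward_backward", "baum_welch_update", "mean_shannon_entropy",
           "posterior_variance"]


@dataclass
class HmmParams:
    """Column-stochastic transition matrix and initial distribution."""

    A: np.ndarray
    pi: np.ndarray

    def __post_init__(self):
        self.A = np.atleast_2d(np.asarray(self.A, dtype=np.float64))
        self.pi = np.asarray(self.pi, dtype=np.float64).ravel()

    @property
    def m(self) -> int:
        return self.A.shape[0]

    def validate(self) -> None:
        A, pi = self.A, self.pi
        if A.shape[0] != A.shape[1] or pi.shape[0] != A.shape[0]:
            raise ValueError("inconsistent HMM shapes")
        if np.any(A < -1e-12) or np.any(A > 1 + 1e-12) or np.any(pi < -1e-12):
            raise ValueError("probabilities must lie in [0, 1]")
        if np.max(np.abs(A.sum(axis=0) - 1.0)) > 1e-10:
            raise ValueError("columns of A must sum to 1")
        if abs(pi.sum() - 1.0) > 1e-10:
            raise ValueError("pi must sum to 1")


@dataclass
class RegimePosterior:
    """Per-timepoint regime posteriors and hard labels."""

    gamma: np.ndarray            # (m, T)
    z: np.ndarray                # (T,) argmax labels
    true_labels: np.ndarray | None = None


@dataclass
class ForwardBackwardResult:
    gamma: np.ndarray            # (m, T) posteriors, columns sum to 1
    xi_sum: np.ndarray           # (m, m) expected transition counts, [to, from]
    log_likelihood: float
    gamma_from_sum: np.ndarray = field(default=None)  # type: ignore
    # sum over t < T-1 of gamma[:, t]; Baum-Welch denominator


def near_diagonal_transitions(m: int, stay: float = 0.9995) -> np.ndarray:
    """The near-diagonal prior transition matrix: `stay` on the diagonal,
    remaining mass split evenly over the other regimes."""
    if m == 1:
        return np.ones((1, 1))
    A = np.full((m, m), (1.0 - stay) / (m - 1))
    np.fill_diagonal(A, stay)
    return A


def uniform_initial(m: int) -> np.ndarray:
    return np.full(m, 1.0 / m)


def simulate_states(hmm: HmmParams, T: int, seed: int | None = None,
                    rng: np.random.Generator | None = None) -> np.ndarray:
    """Sample a regime-label path of length T from the chain."""
    hmm.validate()
    if T < 1:
        raise ValueError("T must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    cum_pi = np.cumsum(hmm.pi)
    cum_A = np.cumsum(hmm.A, axis=0)     # per-column CDFs
    u = rng.random(T)
    labels = np.empty(T, dtype=np.int64)
    s = int(np.searchsorted(cum_pi, u[0], side="right"))
    labels[0] = min(s, hmm.m - 1)
    for t in range(1, T):
        col = cum_A[:, labels[t - 1]]
        labels[t] = min(int(np.searchsorted(col, u[t], side="right")), hmm.m - 1)
    return labels


def forward_backward(hmm: HmmParams, lik: np.ndarray) -> ForwardBackwardResult:
    """Scaled forward-backward on unnormalized emission likelihoods.

    Parameters
    ----------
    lik : (m, T) nonnegative array; column t holds the emission weight of
        each regime at time t.  A column of all zeros is an error.
    """
    lik = np.atleast_2d(np.asarray(lik, dtype=np.float64))
    m, T = lik.shape
    if m != hmm.m:
        raise ValueError("likelihood rows must match number of regimes")
    if np.any(lik < 0):
        raise ValueError("likelihoods must be nonnegative")

    A, pi = hmm.A, hmm.pi
    alpha = np.empty((m, T))
    c = np.empty(T)

    a = pi * lik[:, 0]
    c[0] = a.sum()
    if c[0] <= 0:
        raise ValueError("all-zero likelihood column at timepoint 0")
    alpha[:, 0] = a / c[0]
    for t in range(1, T):
        a = lik[:, t] * (A @ alpha[:, t - 1])
        c[t] = a.sum()
        if c[t] <= 0:
            raise ValueError(f"all-zero likelihood column at timepoint {t}")
        alpha[:, t] = a / c[t]

    beta = np.empty((m, T))
    beta[:, T - 1] = 1.0
    xi_sum = np.zeros((m, m))
    for t in range(T - 2, -1, -1):
        w = lik[:, t + 1] * beta[:, t + 1]
        beta[:, t] = (A.T @ w) / c[t + 1]
        xi = A * np.outer(w, alpha[:, t]) / c[t + 1]   # [to, from]
        s = xi.sum()
        if s > 0:
            xi /= s
        xi_sum += xi

    gamma = alpha * beta
    gamma /= gamma.sum(axis=0, keepdims=True)
    gamma_from_sum = gamma[:, : T - 1].sum(axis=1) if T > 1 else np.zeros(m)
    return ForwardBackwardResult(gamma=gamma, xi_sum=xi_sum,
                                 log_likelihood=float(np.sum(np.log(c))),
                                 gamma_from_sum=gamma_from_sum)


def baum_welch_update(hmm: HmmParams, lik: np.ndarray,
                      fb: ForwardBackwardResult | None = None) -> HmmParams:
    """One EM M-step for (A, pi) from forward-backward statistics.

    A regime that is (numerically) never occupied keeps its prior column of
    A, preserving column-stochasticity.
    """
    if fb is None:
        fb = forward_backward(hmm, lik)
    m = hmm.m
    A_new = hmm.A.copy()
    for j in range(m):
        denom = fb.gamma_from_sum[j]
        if denom > 1e-12:
            A_new[:, j] = fb.xi_sum[:, j] / denom
    # renormalize against floating-point drift
    A_new /= A_new.sum(axis=0, keepdims=True)
    pi_new = fb.gamma[:, 0].copy()
    pi_new /= pi_new.sum()
    out = HmmParams(A_new, pi_new)
    out.validate()
    return out


def mean_shannon_entropy(gamma: np.ndarray) -> float:
    """Mean over time of the Shannon entropy (natural log) of the regime
    posterior, with 0 log 0 = 0."""
    gamma = np.atleast_2d(np.asarray(gamma, dtype=np.float64))
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(gamma > 0, gamma * np.log(gamma), 0.0)
    return float(-terms.sum(axis=0).mean())


def posterior_variance(gamma: np.ndarray) -> np.ndarray:
    """Temporal variance of each regime's posterior trajectory."""
    gamma = np.atleast_2d(np.asarray(gamma, dtype=np.float64))
    return gamma.var(axis=1)
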