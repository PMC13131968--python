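"""Blind identification outer loop.

Alternates (i) inner-loop backpropagated Kalman fitting under the current
regime labels, (ii) per-regime filtering of the whole sequence to obtain
inverted-residual emission likelihoods, (iii) forward-backward posterior
estimation with a K-means fallback when the posteriors collapse onto a
single regime, and (iv) a Baum-Welch update of the transition matrix and
initial distribution — until the regime posterior reaches a low mean
Shannon entropy, after which labels are frozen and only the model
parameters are refined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

from .hmm import (HmmParams, forward_backward, baum_welch_update,
                  mean_shannon_entropy, posterior_variance,
                  near_diagonal_transitions, uniform_initial, simulate_states)
from .kalman import FitConfig, FilterTrace, filter_sequence, fit_inner_loop
from .model import (ModelParams, ObservationModel, canonicalize_modulation,
                    make_mask, project_constraints)
from .optim import NAdam

__all__ = ["BlindConfig", "BlindFitResult", "residual_likelihoods",
           "kmeans_fallback", "init_model_params", "hm_mindy_fit"]

log = logging.getLogger("hmmindy")

MIN_RECOMMENDED_T = 5000


@dataclass
class BlindConfig:
    """Outer-loop settings.

    delta is the posterior-variance threshold below which (for every
    regime) the K-means fallback is used; epsilon the mean-entropy
    stopping threshold.
    """

    m: int = 2
    delta: float = 0.1
    epsilon: float = 0.15
    n_max: int = 50
    smooth_window: int = 250
    floor: float = 1e-8
    seed: int = 0
    fit: FitConfig = field(default_factory=FitConfig)
    post_converge_iters: int = 5
    final_passes: int = 4         # inner passes per post-convergence iteration
    lr_decay: float = 0.88        # learning-rate decay per outer iteration
    lr_min: float = 1e-3
    init_w_scale: float = 0.25
    init_g_jitter: float = 0.02

    def __post_init__(self):
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.delta <= 0 or self.epsilon <= 0:
            raise ValueError("delta and epsilon must be positive")
        if self.n_max < 1:
            raise ValueError("n_max must be >= 1")


@dataclass
class BlindFitResult:
    labels: np.ndarray            # (T,) hard regime labels
    hmm: HmmParams
    params: ModelParams
    trace: FilterTrace
    gamma: np.ndarray | None      # (m, T) final regime posteriors
    diagnostics: pd.DataFrame
    converged: bool
    n_iter: int


def residual_likelihoods(params: ModelParams, obs: ObservationModel,
                         Y: np.ndarray, floor: float = 1e-8):
    """Emission likelihoods from per-regime whole-sequence filtering.

    For each regime i, filter the entire sequence holding Gamma_i active
    throughout, and set lik[i, t] = 1 / max(||resid_t(i)||_2, floor).

    Returns (lik, resid_norms), both (m, T).
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=np.float64))
    T = Y.shape[1]
    m = params.m
    norms = np.empty((m, T))
    for i in range(m):
        trace = filter_sequence(params, obs, Y, np.full(T, i, dtype=np.int64))
        norms[i] = trace.resid_norms
    lik = 1.0 / np.maximum(norms, floor)
    return lik, norms


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x.copy()
    kernel = np.ones(window) / window
    pad = window // 2
    xp = np.pad(x, ((0, 0), (pad, pad)), mode="edge")
    out = np.apply_along_axis(lambda r: np.convolve(r, kernel, mode="valid"),
                              1, xp)
    return out[:, : x.shape[1]]


def kmeans_fallback(resid_norms: np.ndarray, cfg: BlindConfig,
                    rng: np.random.Generator) -> np.ndarray:
    """Cluster temporally smoothed per-regime residual traces into m
    regimes; used to re-seed the labels when the regime posterior has
    collapsed.

    Clusters are mapped to regimes bijectively, minimizing the mean
    residual of the assigned regime within each cluster.  If K-means fails
    to produce m non-empty clusters, a fresh random label path is drawn
    from the prior chain instead (with a warning).
    """
    m, T = resid_norms.shape
    if m < 2:
        raise ValueError("kmeans fallback needs m >= 2")
    smooth = _moving_average(resid_norms, int(cfg.smooth_window))
    km = KMeans(n_clusters=m, n_init=5,
                random_state=int(rng.integers(2**31 - 1)))
    assign = km.fit_predict(smooth.T)
    counts = np.bincount(assign, minlength=m)
    if np.any(counts == 0):
        log.warning("K-means produced an empty cluster; drawing random labels")
        prior = HmmParams(near_diagonal_transitions(m), uniform_initial(m))
        return simulate_states(prior, T, rng=rng)
    cost = np.empty((m, m))        # cluster k x regime i -> mean residual
    for k in range(m):
        sel = assign == k
        cost[k] = smooth[:, sel].mean(axis=1)
    rows, cols = linear_sum_assignment(cost)
    mapping = np.empty(m, dtype=np.int64)
    mapping[rows] = cols
    return mapping[assign]


def init_model_params(n_exc: int, m: int, mask: np.ndarray | None,
                      rng: np.random.Generator,
                      w_scale: float = 0.25, g_jitter: float = 0.02,
                      d_means=(0.66, 0.81), s_values=(2.5, 1.0)) -> ModelParams:
    """Random fitting initialization.

    Connection magnitudes start small and positive, modulation vectors
    start near 1 (Gamma ~= 11^T, so regimes begin nearly symmetric), decay
    and slope start at the values typical of the excitatory/inhibitory
    populations being modeled, and offsets/biases start at zero.
    """
    n_inh = n_exc
    n = n_exc + n_inh
    if mask is None:
        mask = make_mask(n_exc, n_inh, rng)
    W = np.zeros((n, n))
    W[:, :n_exc] = w_scale * rng.random((n, n_exc)) * mask
    diag = w_scale * rng.random(n_exc)
    W[:n_exc, n_exc:] = -np.diag(diag)
    W[n_exc:, n_exc:] = -np.diag(w_scale * rng.random(n_inh))
    g = 1.0 + g_jitter * rng.standard_normal((m, n))
    D = np.concatenate([np.full(n_exc, d_means[0]), np.full(n_inh, d_means[1])])
    S = np.concatenate([np.full(n_exc, s_values[0]), np.full(n_inh, s_values[1])])
    params = ModelParams(n_exc, n_inh, W, g, D, S, np.zeros(n), np.zeros(n),
                         mask)
    return project_constraints(params)


def hm_mindy_fit(Y: np.ndarray, cfg: BlindConfig,
                 obs_init: ObservationModel,
                 mask: np.ndarray | None = None,
                 init_params: ModelParams | None = None) -> BlindFitResult:
    """Blind joint identification of regime labels, HMM parameters and the
    modulated dynamical model from multichannel observations.

    Parameters
    ----------
    Y : (c, T) observation matrix (channels x time).
    cfg : BlindConfig with the outer- and inner-loop settings.
    obs_init : lead field and noise covariances (held fixed).
    mask : optional structural mask for the fitted W; random if omitted.
    init_params : optional explicit model initialization.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=np.float64))
    c, T = Y.shape
    if T < MIN_RECOMMENDED_T:
        log.warning("recording has %d timepoints; accuracy degrades below %d",
                    T, MIN_RECOMMENDED_T)
    rng = np.random.default_rng(cfg.seed)
    m = cfg.m

    hmm = HmmParams(near_diagonal_transitions(m), uniform_initial(m))
    if init_params is None:
        params = init_model_params(c, m, mask, rng,
                                   w_scale=cfg.init_w_scale,
                                   g_jitter=cfg.init_g_jitter)
    else:
        params = project_constraints(init_params)
    z = simulate_states(hmm, T, rng=rng)
    optimizer = NAdam(lr=cfg.fit.lr, betas=cfg.fit.betas)

    gamma = None
    entropy = np.inf
    used_kmeans = True
    converged = False
    records = []
    trace = None
    n_iter = 0

    for it in range(1, cfg.n_max + 1):
        n_iter = it
        optimizer.lr = max(cfg.fit.lr * cfg.lr_decay ** (it - 1), cfg.lr_min)
        params, trace, optimizer = fit_inner_loop(
            params, obs_init, Y, z, cfg.fit, optimizer)

        if gamma is not None and entropy <= cfg.epsilon and not used_kmeans:
            converged = True
            break

        lik, norms = residual_likelihoods(params, obs_init, Y, cfg.floor)
        fb = forward_backward(hmm, lik)
        gamma = fb.gamma
        entropy = mean_shannon_entropy(gamma)
        pv = posterior_variance(gamma)
        z_old = z
        if m >= 2 and np.all(pv < cfg.delta):
            z = kmeans_fallback(norms, cfg, rng)
            used_kmeans = True
        else:
            z = np.argmax(gamma, axis=0).astype(np.int64)
            used_kmeans = False
        hmm = baum_welch_update(hmm, lik, fb)
        records.append({
            "iteration": it, "loss": trace.loss, "mean_entropy": entropy,
            "min_posterior_variance": float(pv.min()),
            "used_kmeans": used_kmeans,
            "label_changes": int(np.sum(z != z_old)),
        })

    if converged:
        from dataclasses import replace as _rep
        refine = _rep(cfg.fit, passes=cfg.final_passes)
        for _ in range(max(0, cfg.post_converge_iters - 1)):
            n_iter += 1
            optimizer.lr = max(optimizer.lr * cfg.lr_decay, cfg.lr_min)
            params, trace, optimizer = fit_inner_loop(
                params, obs_init, Y, z, refine, optimizer)
    else:
        log.warning("outer loop reached n_max=%d without entropy convergence",
                    cfg.n_max)

    params = canonicalize_modulation(params)
    diagnostics = pd.DataFrame.from_records(records)
    hmm.validate()
    params.validate()
    return BlindFitResult(labels=z, hmm=hmm, params=params, trace=trace,
                          gamma=gamma, diagnostics=diagnostics,
                          converged=converged, n_iter=n_iter)
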