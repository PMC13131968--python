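"""Extended Kalman filtering and gradient-based parameter updates.

This is the inner loop of the blind-identification procedure: filter the
observations under a given regime-label sequence, score one-step predictive
quality (covariance-whitened innovations by default; plain innovations or
a-posteriori residuals as options), and descend that loss with NAdam,
backpropagating through the filter recursion ("backpropagated Kalman
filter").

Two differentiation modes are available (``FitConfig.cov_mode``):

``"detached"`` (default)
    Gains and covariances are computed exactly in the forward pass but held
    constant in the backward pass; gradients flow through the state
    recursion only.  Hand-derived adjoint, numba-accelerated.
``"full"``
    The covariance recursion itself is part of the differentiable graph
    (tape-based reverse mode).  Exact but much slower; intended for small
    problems and gradient verification.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as _dc_replace

import numpy as np

from . import _kernels, autodiff as ad
from .model import ModelParams, ObservationModel, project_constraints
from .optim import NAdam, clip_global_norm

__all__ = ["FilterTrace", "FitConfig", "ekf_step", "filter_sequence",
           "loss_and_grads", "fit_inner_loop"]

# parameters the optimizer may update, in a fixed order
_FITTABLE = ("W", "g", "D", "C", "S", "V")


@dataclass
class FilterTrace:
    """Output of a filtering pass."""

    xhat: np.ndarray              # (n, T) a-posteriori state means
    resid: np.ndarray             # (c, T) a-posteriori residuals
    loss: float                   # sum_t ||resid_t||^2
    P_final: np.ndarray           # (n, n) final covariance

    @property
    def resid_norms(self) -> np.ndarray:
        return np.linalg.norm(self.resid, axis=0)


@dataclass
class FitConfig:
    """Inner-loop optimizer settings."""

    lr: float = 1e-2
    betas: tuple = (0.9, 0.999)
    passes: int = 2               # full sweeps through the data per call
    chunk: int = 250              # timepoints per gradient update
    clip: float = 10.0            # global gradient-norm bound
    cov_mode: str = "detached"    # "detached" | "full"
    loss: str = "mahalanobis"     # "mahalanobis" | "innovation" | "posterior"
    fit_fields: tuple = ("W", "g", "D", "C", "S", "V")
    g_anchor: float = 100.0       # ridge weight pulling g toward 1 (per sweep)
    seed: int = 0

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        if self.cov_mode not in ("detached", "full"):
            raise ValueError("cov_mode must be 'detached' or 'full'")
        if self.loss not in ("mahalanobis", "innovation", "posterior"):
            raise ValueError(
                "loss must be 'mahalanobis', 'innovation' or 'posterior'")
        bad = set(self.fit_fields) - set(_FITTABLE)
        if bad:
            raise ValueError(f"unknown fit fields: {sorted(bad)}")


def ekf_step(params: ModelParams, obs: ObservationModel, xhat: np.ndarray,
             P: np.ndarray, y: np.ndarray, regime: int):
    """One EKF predict/update step.

    The dynamics are linearized at the current posterior mean ``xhat``:
    ``F = (W o Gamma) diag(S (1 - tanh^2)) + diag(D)``.

    Returns ``(xhat', P', resid)`` with ``resid = y - H xhat'`` the
    a-posteriori residual.
    """
    n = params.n
    xhat = np.asarray(xhat, dtype=np.float64).reshape(n)
    P = np.asarray(P, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).reshape(obs.n_channels)
    gr = params.g[int(regime)]
    Wg = params.W * np.outer(gr, gr)

    th = np.tanh(params.S * xhat + params.V)
    xp = Wg @ th + params.D * xhat + params.C
    F = Wg * (params.S * (1.0 - th * th)) + np.diag(params.D)
    Pp = F @ P @ F.T + obs.Q
    HP = obs.H @ Pp
    Sin = HP @ obs.H.T + obs.R
    try:
        K = np.linalg.solve(Sin, HP).T
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "innovation covariance is singular; add regularization to R"
        ) from err
    x_new = xp + K @ (y - obs.H @ xp)
    P_new = Pp - K @ HP
    P_new = 0.5 * (P_new + P_new.T)
    resid = y - obs.H @ x_new
    return x_new, P_new, resid


def filter_sequence(params: ModelParams, obs: ObservationModel,
                    Y: np.ndarray, labels: np.ndarray,
                    x0: np.ndarray | None = None,
                    P0: np.ndarray | None = None) -> FilterTrace:
    """Run the EKF over a full sequence with per-timepoint regimes."""
    Y = np.atleast_2d(np.asarray(Y, dtype=np.float64))
    labels = np.ascontiguousarray(labels, dtype=np.int64)
    if labels.shape[0] != Y.shape[1]:
        raise ValueError("labels and observations disagree in length")
    if np.any(labels < 0) or np.any(labels >= params.m):
        raise ValueError("labels out of regime range")
    n = params.n
    x0 = np.zeros(n) if x0 is None else np.asarray(x0, dtype=np.float64)
    P0 = np.eye(n) if P0 is None else np.asarray(P0, dtype=np.float64)

    loss, x, P, th, xprev, K, xhat, resid, innov = _kernels.ekf_forward(
        params.modulated_W(), params.D, params.S, params.V, params.C,
        obs.H, obs.Q, obs.R, labels, np.ascontiguousarray(Y), x0, P0, 0)
    if not np.isfinite(loss):
        bad = np.flatnonzero(~np.all(np.isfinite(xhat), axis=1))
        t = int(bad[0]) if bad.size else -1
        raise FloatingPointError(f"filter state became non-finite at timestep {t}")
    return FilterTrace(xhat=xhat.T.copy(), resid=resid.T.copy(),
                       loss=float(loss), P_final=P)


def _grads_to_params(params: ModelParams, gWg, gD, gS, gV, gC) -> dict:
    """Map effective-connectivity gradients back onto (W, g) and zero the
    structurally fixed entries of W."""
    Gam = params.Gamma
    gW = np.einsum("kij,kij->ij", gWg, Gam)
    gG = gWg * params.W[None, :, :]
    # dL/dg_i = (dGamma_i + dGamma_i^T) g_i for Gamma_i = g_i g_i^T
    gg = np.einsum("kij,kj->ki", gG, params.g) \
        + np.einsum("kji,kj->ki", gG, params.g)
    ne = params.n_exc
    struct = np.zeros_like(gW, dtype=bool)
    struct[:, :ne] = params.mask
    struct[:ne, ne:] = np.eye(ne, params.n_inh, dtype=bool)
    struct[ne:, ne:] = np.eye(params.n_inh, dtype=bool)
    gW[~struct] = 0.0
    return {"W": gW, "g": gg, "D": gD, "S": gS, "V": gV, "C": gC}


def loss_and_grads(params: ModelParams, obs: ObservationModel, Y: np.ndarray,
                   labels: np.ndarray, x0: np.ndarray, P0: np.ndarray,
                   cov_mode: str = "detached", loss: str = "mahalanobis"):
    """Loss and parameter gradients over one chunk.

    Returns ``(loss, grads, x_end, P_end)`` where grads is a dict over
    W, g, D, C, S, V.  In ``"detached"`` mode gains are constants of the
    backward pass; in ``"full"`` mode the covariance recursion is
    differentiated too.
    """
    labels = np.ascontiguousarray(labels, dtype=np.int64)
    Y = np.ascontiguousarray(np.atleast_2d(Y), dtype=np.float64)
    kind = {"posterior": 0, "innovation": 1, "mahalanobis": 2}[loss]
    if cov_mode == "detached":
        Wg = params.modulated_W()
        lval, x, P, th, xprev, K, xhat, resid, innov = _kernels.ekf_forward(
            Wg, params.D, params.S, params.V, params.C,
            obs.H, obs.Q, obs.R, labels, Y, x0, P0, kind)
        gWg, gD, gS, gV, gC = _kernels.ekf_backward(
            Wg, params.D, params.S, obs.H, labels, th, xprev, K, resid,
            innov, kind)
        grads = _grads_to_params(params, gWg, gD, gS, gV, gC)
        return float(lval), grads, x, P
    return _loss_and_grads_tape(params, obs, Y, labels, x0, P0, kind)


def _loss_and_grads_tape(params, obs, Y, labels, x0, P0, loss_kind=1):
    """Tape-based exact gradients with the covariance update in the graph."""
    n, c = params.n, obs.n_channels
    T = Y.shape[1]
    leaves = {
        "W": ad.Var(params.W),
        "g": ad.Var(params.g),
        "D": ad.Var(params.D.reshape(n, 1)),
        "S": ad.Var(params.S.reshape(n, 1)),
        "V": ad.Var(params.V.reshape(n, 1)),
        "C": ad.Var(params.C.reshape(n, 1)),
    }
    I = ad.constant(np.eye(n))
    Hc = ad.constant(obs.H)
    Qc = ad.constant(obs.Q)
    Rc = ad.constant(obs.R)
    Wg = []
    for i in range(params.m):
        gi = ad.reshape(_row(leaves["g"], i, params.m), (n, 1))
        Wg.append(leaves["W"] * ad.matmul(gi, ad.transpose(gi)))
    x = ad.constant(x0.reshape(n, 1))
    P = ad.constant(P0)
    loss = ad.constant(0.0)
    D, S, V, C = (leaves[k] for k in ("D", "S", "V", "C"))
    for t in range(T):
        i = int(labels[t])
        th = ad.tanh(S * x + V)
        xp = ad.matmul(Wg[i], th) + D * x + C
        F = Wg[i] * ad.transpose(S * (ad.constant(1.0) - th * th)) + I * D
        Pp = ad.matmul(ad.matmul(F, P), ad.transpose(F)) + Qc
        HP = ad.matmul(Hc, Pp)
        Sin = ad.matmul(HP, ad.transpose(Hc)) + Rc
        K = ad.transpose(ad.solve(Sin, HP))
        y = ad.constant(Y[:, t].reshape(c, 1))
        innov = y - ad.matmul(Hc, xp)
        x = xp + ad.matmul(K, innov)
        P = Pp - ad.matmul(K, HP)
        if loss_kind == 2:   # innovation-covariance-weighted (Mahalanobis)
            loss = loss + ad.matmul(ad.transpose(innov),
                                    ad.solve(Sin, innov))
        elif loss_kind == 1:
            loss = loss + ad.sumsq(innov)
        else:
            loss = loss + ad.sumsq(y - ad.matmul(Hc, x))
    loss = ad.reshape(loss, ()) if loss.value.ndim else loss
    loss.backward()
    grads = {}
    for k, leaf in leaves.items():
        g = leaf.grad if leaf.grad is not None else np.zeros_like(leaf.value)
        grads[k] = g.reshape(params.g.shape) if k == "g" else g.reshape(
            params.W.shape if k == "W" else (n,))
    ne = params.n_exc
    struct = np.zeros_like(grads["W"], dtype=bool)
    struct[:, :ne] = params.mask
    struct[:ne, ne:] = np.eye(ne, params.n_inh, dtype=bool)
    struct[ne:, ne:] = np.eye(params.n_inh, dtype=bool)
    grads["W"][~struct] = 0.0
    return float(loss.value), grads, x.value.reshape(n), P.value


def _row(v: ad.Var, i: int, m: int) -> ad.Var:
    """Select row i of an (m, n) Var via a constant selector product."""
    sel = np.zeros((1, m))
    sel[0, i] = 1.0
    return ad.matmul(ad.constant(sel), v)


def fit_inner_loop(params: ModelParams, obs: ObservationModel, Y: np.ndarray,
                   labels: np.ndarray, cfg: FitConfig,
                   optimizer: NAdam | None = None):
    """Sweep the data in chunks, one NAdam update per chunk, with the
    constraint projection applied after every update.

    The filter state (x, P) is carried across chunk boundaries;
    backpropagation is truncated at each boundary.  Returns
    ``(params, trace, optimizer)`` where trace is a clean filtering pass
    with the final parameters.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=np.float64))
    labels = np.ascontiguousarray(labels, dtype=np.int64)
    T = Y.shape[1]
    n = params.n
    if optimizer is None:
        optimizer = NAdam(lr=cfg.lr, betas=cfg.betas)
    p = project_constraints(params)
    values = {k: getattr(p, k).copy() for k in _FITTABLE}
    edges = list(range(0, T, max(1, int(cfg.chunk)))) + [T]

    for _ in range(max(0, int(cfg.passes))):
        x = np.zeros(n)
        P = np.eye(n)
        for a, b in zip(edges[:-1], edges[1:]):
            cur = _dc_replace(p, **{k: values[k] for k in _FITTABLE})
            loss, grads, x, P = loss_and_grads(
                cur, obs, Y[:, a:b], labels[a:b], x, P, cfg.cov_mode,
                cfg.loss)
            grads = {k: grads[k] for k in cfg.fit_fields}
            if "g" in grads and cfg.g_anchor > 0:
                # the modulated model has an exact rescaling degeneracy
                # (W, g_i) -> (W / u u^T, g_i o u); a light ridge toward
                # g = 1 selects the canonical near-unity representative
                grads["g"] = grads["g"] + (
                    2.0 * cfg.g_anchor * (b - a) / T) * (values["g"] - 1.0)
            for gmat in grads.values():
                np.nan_to_num(gmat, copy=False)
            clip_global_norm(grads, cfg.clip)
            optimizer.step(values, grads)
            proj = project_constraints(
                _dc_replace(p, **{k: values[k] for k in _FITTABLE}))
            for k in _FITTABLE:
                values[k] = getattr(proj, k)
    out = project_constraints(_dc_replace(p, **{k: values[k] for k in _FITTABLE}))
    trace = filter_sequence(out, obs, Y, labels)
    return out, trace, optimizer
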