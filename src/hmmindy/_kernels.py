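"""Hot loops of the backpropagated Kalman filter.

Two kernels: a forward extended-Kalman pass that stores everything the
adjoint needs, and a reverse (BPTT) pass that accumulates parameter
gradients with the Kalman gains held fixed ("detached covariance").
The training loss is selectable: squared innovations (a-priori prediction
errors, ``loss_kind=1``) or squared a-posteriori residuals
(``loss_kind=0``).  Both are numba-jitted when numba is importable and
fall back to the same pure-python bodies otherwise.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit
    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


@njit(cache=True)
def ekf_forward(Wg, D, S, V, C, H, Q, R, labels, Y, x0, P0, loss_kind):
    """EKF forward pass over one chunk.

    Returns loss, final (x, P) and the per-step tapes needed by the
    adjoint: pre-step states, tanh activations, gains, a-posteriori states
    and both residual kinds.
    """
    n = x0.shape[0]
    c = Y.shape[0]
    T = Y.shape[1]
    th = np.empty((T, n))
    xprev = np.empty((T, n))
    K = np.empty((T, n, c))
    xhat = np.empty((T, n))
    resid = np.empty((T, c))
    innov = np.empty((T, c))   # whitened by Sin when loss_kind == 2
    x = x0.copy()
    P = P0.copy()
    loss = 0.0
    for t in range(T):
        i = labels[t]
        for a in range(n):
            xprev[t, a] = x[a]
        u = S * x + V
        tht = np.tanh(u)
        for a in range(n):
            th[t, a] = tht[a]
        xp = Wg[i] @ tht + D * x + C
        dd = S * (1.0 - tht * tht)
        F = Wg[i] * dd
        for a in range(n):
            F[a, a] += D[a]
        Pp = F @ P @ F.T + Q
        HP = H @ Pp
        Sin = HP @ H.T + R
        Kt = np.linalg.solve(Sin, HP).T
        for a in range(n):
            for b in range(c):
                K[t, a, b] = Kt[a, b]
        y = Y[:, t].copy()
        iv = y - H @ xp
        x = xp + Kt @ iv
        P = Pp - Kt @ HP
        P = 0.5 * (P + P.T)
        r = y - H @ x
        if loss_kind == 2:
            wiv = np.linalg.solve(Sin, iv)
            loss += iv @ wiv
            for b in range(c):
                innov[t, b] = wiv[b]
        elif loss_kind == 1:
            loss += iv @ iv
            for b in range(c):
                innov[t, b] = iv[b]
        else:
            loss += r @ r
            for b in range(c):
                innov[t, b] = iv[b]
        for b in range(c):
            resid[t, b] = r[b]
        for a in range(n):
            xhat[t, a] = x[a]
    return loss, x, P, th, xprev, K, xhat, resid, innov


@njit(cache=True)
def ekf_backward(Wg, D, S, H, labels, th, xprev, K, resid, innov, loss_kind):
    """Adjoint of the filtering loss with gains K held constant.

    Gradients are with respect to the per-regime effective connectivity
    Wg_i = W o Gamma_i and the vectors D, S, V, C.
    """
    T = th.shape[0]
    n = th.shape[1]
    m = Wg.shape[0]
    gWg = np.zeros((m, n, n))
    gD = np.zeros(n)
    gS = np.zeros(n)
    gV = np.zeros(n)
    gC = np.zeros(n)
    lam = np.zeros(n)
    for t in range(T - 1, -1, -1):
        i = labels[t]
        if loss_kind >= 1:
            # x_t = (I - K H) xp + K y; loss term on the (possibly
            # covariance-whitened) innovation y - H xp
            psi = lam - H.T @ (K[t].T @ lam) - 2.0 * (H.T @ innov[t])
        else:
            # loss term ||y - H x_t||^2 with x_t = (I - K H) xp + K y
            lam_bar = lam - 2.0 * (H.T @ resid[t])
            psi = lam_bar - H.T @ (K[t].T @ lam_bar)
        tht = th[t]
        xm = xprev[t]
        for a in range(n):
            pa = psi[a]
            for b in range(n):
                gWg[i, a, b] += pa * tht[b]
        gC += psi
        gD += psi * xm
        e = (Wg[i].T @ psi) * (1.0 - tht * tht)
        gS += e * xm
        gV += e
        lam = D * psi + S * e
    return gWg, gD, gS, gV, gC


@njit(cache=True)
def ekf_forward_frozen_gains(Wg, D, S, V, C, H, labels, Y, x0, K, loss_kind):
    """Loss replay with a fixed gain sequence; used to validate the adjoint."""
    n = x0.shape[0]
    T = Y.shape[1]
    x = x0.copy()
    loss = 0.0
    for t in range(T):
        i = labels[t]
        tht = np.tanh(S * x + V)
        xp = Wg[i] @ tht + D * x + C
        y = Y[:, t].copy()
        iv = y - H @ xp
        x = xp + K[t] @ iv
        r = y - H @ x
        if loss_kind == 1:
            loss += iv @ iv
        else:
            loss += r @ r
    return loss


def warmup(n: int = 3, c: int = 2, m: int = 2) -> None:
    """Trigger JIT compilation on a tiny instance (no-op without numba)."""
    rng = np.random.default_rng(0)
    Wg = 0.1 * rng.random((m, n, n))
    D = np.full(n, 0.5)
    S = np.ones(n)
    V = np.zeros(n)
    C = np.zeros(n)
    H = rng.random((c, n))
    Q = 0.1 * np.eye(n)
    R = 0.1 * np.eye(c)
    labels = np.zeros(4, dtype=np.int64)
    Y = rng.random((c, 4))
    for kind in (0, 1, 2):
        out = ekf_forward(Wg, D, S, V, C, H, Q, R, labels, Y,
                          np.zeros(n), np.eye(n), kind)
        ekf_backward(Wg, D, S, H, labels, out[3], out[4], out[5], out[7],
                     out[8], kind)
        ekf_forward_frozen_gains(Wg, D, S, V, C, H, labels, Y, np.zeros(n),
                                 out[5], kind)
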