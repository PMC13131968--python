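"""Modulated excitatory/inhibitory mesoscale dynamical model.

The model describes ``n = n_exc + n_inh`` neural populations whose activity
``x_t`` evolves as a discrete-time map

    x_{t+1} = (W o Gamma_i) tanh(S x_t + V) + D x_t + C + eps,      eps ~ N(0, Q)

where ``o`` is the elementwise (Hadamard) product, ``W`` is a signed base
effective-connectivity matrix shared across regimes, and ``Gamma_i`` is a
nonnegative rank-1 modulation matrix selected by the active regime
``i in {0..m-1}``.  ``D`` is a per-population retention (leak) multiplier,
``S`` and ``V`` the slope and offset of the tanh nonlinearity, and ``C`` a
bias.  Because every ``Gamma_i`` is nonnegative, modulation rescales
connection strengths without ever flipping their sign.

Populations are ordered ``[excitatory; inhibitory]`` and ``W`` has the block
structure ``[[Wee, -Wie], [Wei, -Wii]]``: excitatory source columns are
nonnegative, inhibitory source columns nonpositive, and the
inhibitory-source blocks ``Wie``/``Wii`` are diagonal (inhibition is local).
A binary mask fixes 75% of the off-diagonal ``Wee``/``Wei`` entries to zero.

Observations are a linear readout of the excitatory populations only,

    y_t = H x_t + nu,      nu ~ N(0, R),   H = [H_exc  0],

so the system is underdetermined: inhibitory activity is never measured and
must be inferred.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["ModelParams", "ObservationModel", "make_mask", "step_dynamics",
           "observe", "simulate", "project_constraints"]


def make_mask(n_exc: int, n_inh: int, rng: np.random.Generator,
              density: float = 0.25) -> np.ndarray:
    """Random structural mask over the [Wee; Wei] column block.

    Returns a boolean array of shape ``(n_exc + n_inh, n_exc)`` where True
    marks an allowed connection.  The diagonals of both the Wee and Wei
    blocks are always kept; a fraction ``1 - density`` of each block's
    off-diagonal entries is zeroed uniformly at random.
    """
    n = n_exc + n_inh
    mask = np.zeros((n, n_exc), dtype=bool)
    eye = np.eye(n_exc, dtype=bool)
    for block in range(2):  # 0 -> Wee rows, 1 -> Wei rows
        if block == 1 and n_inh == 0:
            break
        rows = slice(0, n_exc) if block == 0 else slice(n_exc, n)
        off = ~eye
        keep = rng.random((n_exc, n_exc)) < density
        mask[rows] = eye | (off & keep)
    return mask


@dataclass
class ModelParams:
    """All fitted neural-model quantities plus structural metadata.

    Attributes
    ----------
    n_exc, n_inh : int
        Population counts; ``n = n_exc + n_inh``.
    W : (n, n) ndarray
        Signed base connectivity ``[[Wee, -Wie], [Wei, -Wii]]``.
    g : (m, n) ndarray
        Modulation generating vectors; ``Gamma_i = g_i g_i^T``.
    D, S, V, C : (n,) ndarray
        Retention, slope, offset and bias vectors.
    mask : (n, n_exc) bool ndarray
        Allowed entries of the excitatory-source column block.
    """

    n_exc: int
    n_inh: int
    W: np.ndarray
    g: np.ndarray
    D: np.ndarray
    S: np.ndarray
    V: np.ndarray
    C: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        n = self.n
        self.W = np.asarray(self.W, dtype=np.float64).reshape(n, n)
        self.g = np.atleast_2d(np.asarray(self.g, dtype=np.float64))
        for name in ("D", "S", "V", "C"):
            setattr(self, name, np.asarray(getattr(self, name),
                                           dtype=np.float64).reshape(n))
        if self.mask is None:
            self.mask = np.ones((n, self.n_exc), dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool).reshape(n, self.n_exc)

    @property
    def n(self) -> int:
        return self.n_exc + self.n_inh

    @property
    def m(self) -> int:
        """Number of regimes (modulation matrices)."""
        return self.g.shape[0]

    @property
    def Gamma(self) -> np.ndarray:
        """Stack of rank-1 modulation matrices, shape (m, n, n)."""
        return np.einsum("ki,kj->kij", self.g, self.g)

    def modulated_W(self) -> np.ndarray:
        """Effective per-regime connectivity W o Gamma_i, shape (m, n, n)."""
        return self.W[None, :, :] * self.Gamma

    # block accessors (magnitudes for the inhibitory-source blocks)
    @property
    def Wee(self):
        return self.W[: self.n_exc, : self.n_exc]

    @property
    def Wei(self):
        return self.W[self.n_exc:, : self.n_exc]

    @property
    def Wie(self):
        return -self.W[: self.n_exc, self.n_exc:]

    @property
    def Wii(self):
        return -self.W[self.n_exc:, self.n_exc:]

    def copy(self) -> "ModelParams":
        return ModelParams(self.n_exc, self.n_inh, self.W.copy(),
                           self.g.copy(), self.D.copy(), self.S.copy(),
                           self.V.copy(), self.C.copy(), self.mask.copy())

    def validate(self) -> None:
        """Raise ValueError if any structural invariant is violated."""
        ne, n = self.n_exc, self.n
        if not np.all(np.isfinite(self.W)) or not np.all(np.isfinite(self.g)):
            raise ValueError("non-finite parameter values")
        if np.any(self.g < 0):
            raise ValueError("modulation vectors must be nonnegative")
        if np.any(self.W[:, :ne][~self.mask] != 0):
            raise ValueError("masked Wee/Wei entries must be exactly zero")
        if np.any(self.W[:, :ne] < 0):
            raise ValueError("excitatory source columns must be >= 0")
        if np.any(self.W[:, ne:] > 0):
            raise ValueError("inhibitory source columns must be <= 0")
        inh = self.W[:, ne:]
        offdiag = inh.copy()
        top = np.eye(ne, self.n_inh, dtype=bool)
        bot = np.eye(self.n_inh, dtype=bool)
        offdiag[:ne][top] = 0.0
        offdiag[ne:][bot] = 0.0
        if np.any(offdiag != 0):
            raise ValueError("Wie/Wii blocks must be diagonal")
        if np.any(self.D < 0):
            raise ValueError("D must be nonnegative")
        if np.any(self.S <= 0):
            raise ValueError("S must be positive")


@dataclass
class ObservationModel:
    """Lead field and noise covariances of the measurement equation."""

    H: np.ndarray  # (c, n)
    Q: np.ndarray  # (n, n) process noise covariance
    R: np.ndarray  # (c, c) measurement noise covariance

    def __post_init__(self):
        self.H = np.atleast_2d(np.asarray(self.H, dtype=np.float64))
        self.Q = np.atleast_2d(np.asarray(self.Q, dtype=np.float64))
        self.R = np.atleast_2d(np.asarray(self.R, dtype=np.float64))

    @property
    def n_channels(self) -> int:
        return self.H.shape[0]

    def validate(self) -> None:
        for name in ("Q", "R"):
            M = getattr(self, name)
            if not np.allclose(M, M.T, atol=1e-10):
                raise ValueError(f"{name} must be symmetric")
            if np.min(np.linalg.eigvalsh(0.5 * (M + M.T))) < -1e-10:
                raise ValueError(f"{name} must be positive semidefinite")


def _check_regime(params: ModelParams, regime: int) -> int:
    regime = int(regime)
    if not 0 <= regime < params.m:
        raise ValueError(f"regime {regime} out of range 0..{params.m - 1}")
    return regime


def step_dynamics(params: ModelParams, x: np.ndarray, regime: int,
                  eps: np.ndarray | float = 0.0) -> np.ndarray:
    """One step of the modulated dynamics under the given regime.

    Returns ``(W o Gamma_regime) tanh(S x + V) + D x + C + eps``.
    """
    regime = _check_regime(params, regime)
    x = np.asarray(x, dtype=np.float64).reshape(params.n)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite state input")
    eps = np.broadcast_to(np.asarray(eps, dtype=np.float64), (params.n,))
    gr = params.g[regime]
    Wg = params.W * np.outer(gr, gr)
    return Wg @ np.tanh(params.S * x + params.V) + params.D * x + params.C + eps


def observe(obs: ObservationModel, x: np.ndarray,
            nu: np.ndarray | float = 0.0) -> np.ndarray:
    """Measurement map ``y = H x + nu``."""
    x = np.asarray(x, dtype=np.float64).reshape(obs.H.shape[1])
    nu = np.broadcast_to(np.asarray(nu, dtype=np.float64), (obs.H.shape[0],))
    return obs.H @ x + nu


def simulate(params: ModelParams, obs: ObservationModel, labels: np.ndarray,
             x0: np.ndarray | None = None, seed: int | None = None,
             rng: np.random.Generator | None = None):
    """Forward-simulate states and observations along a regime-label path.

    Parameters
    ----------
    labels : (T,) int array of regimes in 0..m-1, one per output timepoint.
    x0 : initial state (defaults to zeros).
    seed, rng : either a seed or an existing Generator (rng wins).

    Returns
    -------
    X : (n, T) state trajectory, Y : (c, T) observation trajectory.

    Raises
    ------
    FloatingPointError if the state becomes non-finite, naming the timestep.
    """
    labels = np.asarray(labels, dtype=np.int64)
    T = labels.shape[0]
    if T < 1:
        raise ValueError("need at least one timepoint")
    if np.any(labels < 0) or np.any(labels >= params.m):
        raise ValueError("labels out of regime range")
    if rng is None:
        rng = np.random.default_rng(seed)
    n, c = params.n, obs.n_channels
    x = np.zeros(n) if x0 is None else np.asarray(x0, dtype=np.float64).reshape(n)

    Lq = _chol_psd(obs.Q)
    Lr = _chol_psd(obs.R)
    eps = Lq @ rng.standard_normal((n, T))
    nu = Lr @ rng.standard_normal((c, T))

    Wg = params.modulated_W()
    X = np.empty((n, T))
    for t in range(T):
        i = labels[t]
        x = Wg[i] @ np.tanh(params.S * x + params.V) \
            + params.D * x + params.C + eps[:, t]
        if not np.all(np.isfinite(x)):
            raise FloatingPointError(f"state diverged (non-finite) at timestep {t}")
        X[:, t] = x
    Y = obs.H @ X + nu
    return X, Y


def _chol_psd(M: np.ndarray) -> np.ndarray:
    """Cholesky factor tolerant of PSD (rank-deficient / zero) matrices."""
    M = np.atleast_2d(M)
    try:
        return np.linalg.cholesky(M)
    except np.linalg.LinAlgError:
        w, U = np.linalg.eigh(0.5 * (M + M.T))
        w = np.clip(w, 0.0, None)
        return U * np.sqrt(w)


def project_constraints(params: ModelParams) -> ModelParams:
    """Project parameters onto the feasible set (idempotent).

    Zeroes masked Wee/Wei entries and off-diagonal Wie/Wii entries, restores
    the source-sign pattern by clamping magnitudes at zero, clamps the
    modulation vectors at zero (so every Gamma_i >= 0), and keeps D in
    [0, 1) and S strictly positive so the filtered dynamics stay stable.
    """
    p = params.copy()
    ne, n = p.n_exc, p.n

    exc = p.W[:, :ne]
    exc[~p.mask] = 0.0
    np.clip(exc, 0.0, None, out=exc)

    inh = p.W[:, ne:]
    diag_top = np.eye(ne, p.n_inh, dtype=bool)
    diag_bot = np.eye(p.n_inh, dtype=bool)
    keep = np.zeros_like(inh, dtype=bool)
    keep[:ne] = diag_top
    keep[ne:] = diag_bot
    inh[~keep] = 0.0
    np.clip(inh, None, 0.0, out=inh)

    np.clip(p.g, 0.0, None, out=p.g)
    np.clip(p.D, 0.0, 0.995, out=p.D)
    np.clip(p.S, 1e-6, None, out=p.S)
    return p


def canonicalize_modulation(params: ModelParams) -> ModelParams:
    """Select the canonical representative of the rescaling equivalence
    class.

    The modulated model is exactly invariant under
    ``(W, g_i) -> (W / u u^T, g_i o u)`` for any positive vector ``u``
    (every effective matrix ``W o Gamma_i`` is unchanged), so the common
    per-population level of the modulation vectors is not identifiable.
    This picks ``u`` minimizing ``sum_i ||g_i o u - 1||^2`` (closed form
    ``u_j = sum_i g_ij / sum_i g_ij^2``), i.e. the representative whose
    modulations are closest to unity — matching the convention that
    modulation rescales the base connectivity by amounts near 1.
    """
    p = params.copy()
    num = p.g.sum(axis=0)
    den = (p.g * p.g).sum(axis=0)
    u = np.where(den > 1e-12, num / np.maximum(den, 1e-12), 1.0)
    u = np.clip(u, 1e-6, None)
    p.g *= u
    p.W /= np.outer(u, u)
    return p


def unmodulated(params: ModelParams) -> ModelParams:
    """Return a single-regime copy with Gamma = 11^T (no modulation)."""
    return replace(params.copy(), g=np.ones((1, params.n)))
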