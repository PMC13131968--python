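"""Model/Results front end.

`HMMindy` is constructed from data and configuration; `fit()` runs the
blind identification procedure and returns an `HMMindyResults` carrying
the regime labels, the switching-chain estimates, the dynamical-model
parameters, diagnostics and a `summary()` table, with `simulate()` for
generating data from the fitted model.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .blind import BlindConfig, BlindFitResult, hm_mindy_fit
from .hmm import mean_shannon_entropy
from .io_eeg import Recording, build_eeg_forward_model, write_fit_outputs
from .kalman import FitConfig
from .model import ObservationModel, simulate

__all__ = ["HMMindy", "HMMindyResults"]


class HMMindy:
    """Blind switching excitatory/inhibitory mesoscale dynamics model.

    Parameters
    ----------
    endog : array_like or DataFrame, shape (T, c) or (c, T)
        Multichannel recording.  A DataFrame is interpreted as
        observations x channels; a plain array is assumed channels x time
        when it is wider than tall.
    fs : float
        Sampling rate in Hz (drives the default smoothing window).
    n_regimes : int
        Number of latent regimes m to identify.
    observation : ObservationModel, optional
        Lead field and noise covariances; defaults to the fixed EEG
        surrogate (identity-minus-mean lead field over hidden inhibitory
        populations).
    mask : bool array, optional
        Structural mask for the fitted connectivity; random if omitted.
    config : BlindConfig, optional
        Full control of outer/inner loop settings.
    """

    def __init__(self, endog, fs: float = 250.0, n_regimes: int = 2,
                 observation: ObservationModel | None = None,
                 mask: np.ndarray | None = None,
                 config: BlindConfig | None = None):
        if isinstance(endog, pd.DataFrame):
            self.channel_names = list(endog.columns)
            Y = endog.to_numpy().T
        else:
            Y = np.atleast_2d(np.asarray(endog, dtype=np.float64))
            if Y.shape[0] > Y.shape[1]:   # (T, c) -> (c, T)
                Y = Y.T
            self.channel_names = [f"ch{i}" for i in range(Y.shape[0])]
        self.endog = Y
        self.fs = float(fs)
        self.n_regimes = int(n_regimes)
        self.observation = observation or build_eeg_forward_model(Y.shape[0])
        self.mask = mask
        self.config = config

    @classmethod
    def from_recording(cls, rec: Recording, **kwargs) -> "HMMindy":
        model = cls(rec.data, fs=rec.fs, **kwargs)
        model.channel_names = list(rec.channels)
        return model

    def fit(self, seed: int = 0, **overrides) -> "HMMindyResults":
        """Run blind identification.  Keyword overrides are applied to the
        BlindConfig (outer loop) or FitConfig (inner loop) fields."""
        cfg = self.config or BlindConfig(m=self.n_regimes,
                                         smooth_window=int(self.fs))
        fit_overrides = {k: v for k, v in overrides.items()
                         if k in FitConfig.__dataclass_fields__
                         and k not in BlindConfig.__dataclass_fields__}
        blind_overrides = {k: v for k, v in overrides.items()
                           if k in BlindConfig.__dataclass_fields__}
        unknown = set(overrides) - set(fit_overrides) - set(blind_overrides)
        if unknown:
            raise TypeError(f"unknown fit options: {sorted(unknown)}")
        if fit_overrides:
            blind_overrides["fit"] = replace(cfg.fit, **fit_overrides)
        cfg = replace(cfg, m=self.n_regimes, seed=seed, **blind_overrides)
        res = hm_mindy_fit(self.endog, cfg, self.observation, mask=self.mask)
        return HMMindyResults(self, cfg, res)


class HMMindyResults:
    """Fit results: labels, chain, dynamics, diagnostics."""

    def __init__(self, model: HMMindy, config: BlindConfig,
                 res: BlindFitResult):
        self.model = model
        self.config = config
        self._res = res

    # -- estimates ------------------------------------------------------
    @property
    def labels(self) -> np.ndarray:
        return self._res.labels

    @property
    def regime_probs(self) -> np.ndarray:
        """(m, T) posterior regime probabilities from the final
        forward-backward pass (None before any pass, e.g. m=1)."""
        return self._res.gamma

    @property
    def transition_matrix(self) -> np.ndarray:
        return self._res.hmm.A

    @property
    def initial_probs(self) -> np.ndarray:
        return self._res.hmm.pi

    @property
    def mparams(self):
        return self._res.params

    @property
    def filter_trace(self):
        return self._res.trace

    @property
    def diagnostics(self) -> pd.DataFrame:
        return self._res.diagnostics

    @property
    def converged(self) -> bool:
        return self._res.converged

    @property
    def occupancy(self) -> np.ndarray:
        """Fraction of timepoints assigned to each regime."""
        m = self.config.m
        return np.bincount(self.labels, minlength=m) / self.labels.shape[0]

    def simulate(self, T: int | None = None, labels=None, seed: int = 0):
        """Simulate (states, observations) from the fitted model; labels
        default to a fresh draw from the fitted chain."""
        from .hmm import simulate_states
        if labels is None:
            if T is None:
                T = self.labels.shape[0]
            labels = simulate_states(self._res.hmm, T, seed=seed)
        return simulate(self.mparams, self.model.observation, labels,
                        seed=seed)

    def plot_regimes(self, ax=None, channel: int = 0):
        """Plot one channel of the recording with the inferred regime
        sequence shaded behind it (requires matplotlib)."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots(figsize=(10, 3))
        T = self.labels.shape[0]
        t = np.arange(T) / self.model.fs
        ax.plot(t, self.model.endog[channel], lw=0.5, color="k")
        for i in range(self.config.m):
            ax.fill_between(t, *ax.get_ylim(), where=self.labels == i,
                            alpha=0.15, step="mid",
                            label=f"regime {i}")
        ax.set_xlabel("time (s)")
        ax.set_ylabel(self.model.channel_names[channel])
        ax.legend(loc="upper right", fontsize="small")
        return ax

    def save(self, outdir) -> None:
        write_fit_outputs(outdir, self._res, self.model.observation,
                          seed=self.config.seed)

    def summary(self) -> str:
        res = self._res
        m = self.config.m
        occ = self.occupancy
        lines = [
            "          Blind switching E/I dynamics fit",
            "=" * 58,
            f"Channels:            {self.model.endog.shape[0]:>6d}"
            f"    Populations:     {res.params.n:>6d}",
            f"Timepoints:          {self.model.endog.shape[1]:>6d}"
            f"    Regimes (m):     {m:>6d}",
            f"Outer iterations:    {res.n_iter:>6d}"
            f"    Converged:       {str(res.converged):>6s}",
            f"Filter loss:         {res.trace.loss:>12.4f}",
        ]
        if res.gamma is not None:
            lines.append(
                f"Mean posterior entropy: {mean_shannon_entropy(res.gamma):.4f}"
                f"  (threshold {self.config.epsilon})")
        lines.append("-" * 58)
        lines.append("Transition matrix A (column-stochastic) and occupancy:")
        for i in range(m):
            row = "  ".join(f"{res.hmm.A[i, j]:.4f}" for j in range(m))
            lines.append(f"  [{row}]   regime {i}: {occ[i]:6.1%}")
        lines.append("=" * 58)
        return "\n".join(lines)

    def __repr__(self):
        return (f"<HMMindyResults m={self.config.m} "
                f"converged={self.converged} n_iter={self._res.n_iter}>")
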