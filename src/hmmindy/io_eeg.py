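"""Data ingestion, preprocessing and result serialization.

Recordings are channels x time.  Two input formats are supported: EDF
(through mne, optional dependency) and a delimited numeric matrix with a
YAML sidecar holding the sampling rate and channel names, plus an optional
two-column events TSV (sample, state).

Preprocessing follows the standard alpha-band pipeline: zero-phase
band-pass, per-channel median subtraction, division by the per-channel
mean absolute deviation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import yaml
from scipy import signal as sps

from .model import ModelParams, ObservationModel

__all__ = ["Recording", "read_recording", "write_recording", "preprocess",
           "build_eeg_forward_model", "monte_carlo_mask_selection",
           "save_model_bundle", "load_model_bundle", "write_fit_outputs"]

log = logging.getLogger("hmmindy")


@dataclass
class Recording:
    data: np.ndarray                      # (c, T)
    fs: float
    channels: list = field(default_factory=list)
    events: np.ndarray | None = None      # (k, 2): sample index, state index

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=np.float64))
        if not self.channels:
            self.channels = [f"ch{i}" for i in range(self.data.shape[0])]
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.events is not None:
            ev = np.asarray(self.events, dtype=np.int64).reshape(-1, 2)
            if np.any(np.diff(ev[:, 0]) < 0):
                raise ValueError("events must be sorted by sample index")
            if np.any(ev[:, 0] < 0) or np.any(ev[:, 0] >= self.data.shape[1]):
                raise ValueError("event samples out of range")
            self.events = ev

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def state_labels(self) -> np.ndarray:
        """Per-timepoint state index from the event list (piecewise
        constant, first segment takes the first event's state)."""
        if self.events is None or len(self.events) == 0:
            raise ValueError("recording has no events")
        labels = np.zeros(self.n_samples, dtype=np.int64)
        labels[: self.events[0, 0]] = self.events[0, 1]
        for k in range(len(self.events)):
            stop = (self.events[k + 1, 0] if k + 1 < len(self.events)
                    else self.n_samples)
            labels[self.events[k, 0]: stop] = self.events[k, 1]
        return labels


def read_recording(path, fmt: str | None = None) -> Recording:
    """Read an EDF file or a delimited matrix (+ sidecar) into a Recording.

    The delimited format stores the matrix as time x channels with one
    header row of channel names (transposed to channels x time on read);
    `<stem>.yaml` holds `fs` (Hz) and optionally `channels`;
    `<stem>.events.tsv` may hold (sample, state) events.
    """
    path = Path(path)
    if fmt is None:
        fmt = "edf" if path.suffix.lower() == ".edf" else "tsv"
    if fmt == "edf":
        return _read_edf(path)
    if fmt == "tsv":
        return _read_delimited(path)
    raise ValueError(f"unknown recording format: {fmt!r}")


def _read_edf(path: Path) -> Recording:
    try:
        import mne
    except ImportError as err:  # pragma: no cover
        raise ImportError("EDF support requires mne (install extra 'edf')") from err
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data()
    events = None
    if len(raw.annotations):
        ev = []
        for ann in raw.annotations:
            sample = int(round(ann["onset"] * raw.info["sfreq"]))
            try:
                state = int(float(ann["description"]))
            except ValueError:
                state = len(ev) % 2
            ev.append((min(sample, data.shape[1] - 1), state))
        events = np.asarray(ev, dtype=np.int64)
    return Recording(data=data, fs=float(raw.info["sfreq"]),
                     channels=list(raw.ch_names), events=events)


def _read_delimited(path: Path) -> Recording:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    data = np.loadtxt(path, skiprows=1, delimiter="\t", ndmin=2)
    # stored time x channels (header = channel names); transpose to c x T
    data = data.T
    meta = {}
    side = path.with_suffix(".yaml")
    if side.exists():
        meta = yaml.safe_load(side.read_text()) or {}
    fs = float(meta.get("fs", 1.0))
    channels = meta.get("channels", header)
    if len(channels) != data.shape[0]:
        raise ValueError(
            f"channel count mismatch: {len(channels)} names for "
            f"{data.shape[0]} data rows")
    events = None
    ev_path = path.with_suffix(".events.tsv")
    if ev_path.exists():
        events = np.loadtxt(ev_path, dtype=np.int64, ndmin=2)
    return Recording(data=data, fs=fs, channels=list(channels), events=events)


def write_recording(rec: Recording, path) -> None:
    """Write the delimited representation (matrix + YAML sidecar + events)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(rec.channels) + "\n")
        np.savetxt(fh, rec.data.T, delimiter="\t", fmt="%.10g")
    path.with_suffix(".yaml").write_text(
        yaml.safe_dump({"fs": float(rec.fs), "channels": list(rec.channels)}))
    if rec.events is not None:
        np.savetxt(path.with_suffix(".events.tsv"), rec.events,
                   delimiter="\t", fmt="%d")


def preprocess(rec: Recording, band=(8.0, 12.0), order: int = 4) -> Recording:
    """Zero-phase band-pass, then per-channel median subtraction and mean
    absolute deviation normalization."""
    lo, hi = band
    if not 0 < lo < hi < rec.fs / 2:
        raise ValueError("band must satisfy 0 < lo < hi < fs/2")
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=rec.fs,
                     output="sos")
    filt = sps.sosfiltfilt(sos, rec.data, axis=1)
    med = np.median(filt, axis=1, keepdims=True)
    centered = filt - med
    mad = np.mean(np.abs(centered), axis=1, keepdims=True)
    flat = np.flatnonzero(mad.ravel() == 0)
    if flat.size:
        raise ValueError(
            f"channel {rec.channels[flat[0]]} is constant after filtering")
    return Recording(data=centered / mad, fs=rec.fs,
                     channels=list(rec.channels), events=rec.events)


def build_eeg_forward_model(c: int, q_scale: float = 0.25,
                            r_scale: float = 1.2) -> ObservationModel:
    """Fixed surrogate lead field for c-channel EEG over 2c populations:
    H = [I - 0.05 11^T, 0], Q = q_scale I, R = r_scale I."""
    if c < 1:
        raise ValueError("need at least one channel")
    Hexc = np.eye(c) - 0.05 * np.ones((c, c))
    H = np.hstack([Hexc, np.zeros((c, c))])
    return ObservationModel(H=H, Q=q_scale * np.eye(2 * c),
                            R=r_scale * np.eye(c))


def monte_carlo_mask_selection(rec: Recording, cfg, n_masks: int = 5,
                               seed: int = 0, obs: ObservationModel | None = None):
    """Fit with several independent random structural masks and keep the
    fit whose labels best match the recording's events.

    Returns (best_mask, best_result, best_accuracy, all_accuracies).
    """
    from .blind import hm_mindy_fit
    from .evaluate import aligned_accuracy
    from .model import make_mask
    from dataclasses import replace

    z_true = rec.state_labels()
    if obs is None:
        obs = build_eeg_forward_model(rec.n_channels)
    rng = np.random.default_rng(seed)
    best = (None, None, -1.0)
    accs = []
    for k in range(n_masks):
        mask = make_mask(rec.n_channels, rec.n_channels, rng)
        cfg_k = replace(cfg, seed=int(rng.integers(2**31 - 1)))
        res = hm_mindy_fit(rec.data, cfg_k, obs, mask=mask)
        acc, _, _ = aligned_accuracy(res.labels, z_true, cfg.m)
        accs.append(acc)
        if acc > best[2]:
            best = (mask, res, acc)
    return best[0], best[1], best[2], np.asarray(accs)


def save_model_bundle(path, params: ModelParams, obs: ObservationModel,
                      seed: int | None = None) -> None:
    """Serialize a parameter bundle to a hierarchical HDF5 container."""
    with h5py.File(path, "w") as f:
        f.create_dataset("W", data=params.W)
        for i, G in enumerate(params.Gamma, start=1):
            f.create_dataset(f"Gamma/{i}", data=G)
            f.create_dataset(f"g/{i}", data=params.g[i - 1])
        for name in ("D", "S", "V", "C"):
            f.create_dataset(name, data=getattr(params, name))
        f.create_dataset("mask", data=params.mask.astype(np.uint8))
        f.create_dataset("H", data=obs.H)
        f.create_dataset("Q", data=obs.Q)
        f.create_dataset("R", data=obs.R)
        f.attrs["n_exc"] = params.n_exc
        f.attrs["n_inh"] = params.n_inh
        f.attrs["m"] = params.m
        if seed is not None:
            f.attrs["seed"] = int(seed)


def load_model_bundle(path):
    """Inverse of save_model_bundle: returns (ModelParams, ObservationModel)."""
    with h5py.File(path, "r") as f:
        m = int(f.attrs["m"])
        g = np.stack([f[f"g/{i}"][()] for i in range(1, m + 1)])
        params = ModelParams(int(f.attrs["n_exc"]), int(f.attrs["n_inh"]),
                             f["W"][()], g, f["D"][()], f["S"][()],
                             f["V"][()], f["C"][()],
                             f["mask"][()].astype(bool))
        obs = ObservationModel(f["H"][()], f["Q"][()], f["R"][()])
    return params, obs


def write_fit_outputs(outdir, result, obs: ObservationModel,
                      seed: int | None = None) -> None:
    """Write labels.tsv, hmm.json, params.h5 and diagnostics.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    T = result.labels.shape[0]
    m = result.hmm.m
    gamma = (result.gamma if result.gamma is not None
             else np.full((m, T), np.nan))
    with open(outdir / "labels.tsv", "w") as fh:
        cols = ["sample", "z"] + [f"gamma_{i + 1}" for i in range(m)]
        fh.write("\t".join(cols) + "\n")
        for t in range(T):
            row = [str(t), str(int(result.labels[t]))]
            row += [f"{gamma[i, t]:.6g}" for i in range(m)]
            fh.write("\t".join(row) + "\n")
    (outdir / "hmm.json").write_text(json.dumps({
        "A": result.hmm.A.tolist(), "pi": result.hmm.pi.tolist(),
        "column_stochastic": True, "converged": bool(result.converged),
    }, indent=2))
    save_model_bundle(outdir / "params.h5", result.params, obs, seed=seed)
    result.diagnostics.to_csv(outdir / "diagnostics.tsv", sep="\t",
                              index=False)
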