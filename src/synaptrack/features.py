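"""From raw multichannel recordings to windowed cross-spectral data features.

The analysis path mirrors standard intracranial practice: re-reference to a
bipolar montage (a spatial filter), zero-phase band-pass, cut the peri-onset
epoch into short overlapping windows that are treated as locally stationary,
and estimate a complex cross-spectral density per window on a fixed frequency
grid.

Two spectral estimators are provided: a vector-autoregressive (VAR) estimator
(default; smooth spectra, evaluable at arbitrary frequencies) and a multitaper
cross-periodogram (non-parametric cross-check with exact phase behaviour).
The estimator and its order/taper settings are recorded in the output
metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.signal
import yaml

from .spectral import FrequencyGrid, csd_is_hermitian

__all__ = [
    "Recording",
    "WindowedCSD",
    "read_recording",
    "write_recording_text",
    "bipolar_montage",
    "bandpass",
    "segment_windows",
    "estimate_csd",
]


@dataclass
class Recording:
    """Multichannel time series with labelled channels.

    ``data`` is ``(n_channels, n_samples)`` in recording units (microvolts for
    EEG).  ``annotations`` may carry epoching information such as the seizure
    onset time in seconds.
    """

    labels: list[str]
    fs: float
    data: np.ndarray
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("one label per channel required")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.fs

    def channel(self, label: str) -> np.ndarray:
        try:
            return self.data[self.labels.index(label)]
        except ValueError as exc:
            raise KeyError(f"unknown channel label {label!r}") from exc


def read_recording(path: str | Path, format: str | None = None, fs: float | None = None) -> Recording:
    """Read a recording from EDF or delimited text.

    Text files need a header row of channel labels and the sampling rate,
    either passed as ``fs`` or in a YAML sidecar ``<path>.yaml`` with key
    ``sample_rate``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        suffix = path.suffix.lower()
        format = "edf" if suffix == ".edf" else "text"
    if format == "edf":
        return _read_edf(path)
    if format == "text":
        return _read_text(path, fs)
    raise ValueError(f"unknown format {format!r}; expected 'edf' or 'text'")


def _read_edf(path: Path) -> Recording:
    import mne

    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:
        size = path.stat().st_size
        raise IOError(
            f"failed to parse EDF file {path} ({size} bytes read): {exc}"
        ) from exc
    return Recording(
        labels=list(raw.ch_names),
        fs=float(raw.info["sfreq"]),
        data=raw.get_data() * 1e6,  # volts -> microvolts
    )


def _read_text(path: Path, fs: float | None) -> Recording:
    if fs is None:
        sidecar = Path(str(path) + ".yaml")
        if not sidecar.exists():
            raise ValueError(
                f"sampling rate unknown: pass fs= or provide sidecar {sidecar}"
            )
        meta = yaml.safe_load(sidecar.read_text())
        if "sample_rate" not in meta:
            raise ValueError(f"sidecar {sidecar} lacks 'sample_rate'")
        fs = float(meta["sample_rate"])
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except Exception as exc:
        raise IOError(f"failed to parse {path} at byte offset ~{path.stat().st_size}: {exc}") from exc
    if df.shape[1] < 1 or df.shape[0] < 2:
        raise IOError(f"{path}: no data rows under the header")
    return Recording(labels=[str(c) for c in df.columns], fs=fs, data=df.to_numpy().T)


def write_recording_text(rec: Recording, path: str | Path) -> None:
    """Write a recording as CSV plus a YAML sidecar with the sampling rate."""
    path = Path(path)
    pd.DataFrame(rec.data.T, columns=rec.labels).to_csv(path, index=False)
    Path(str(path) + ".yaml").write_text(yaml.safe_dump({"sample_rate": rec.fs}))


def bipolar_montage(rec: Recording, pairs: list[tuple[str, str]]) -> Recording:
    """Re-reference to bipolar derivations: each output is ``first - second``.

    Output channels are labelled ``"A-B"``.  Acts as a spatial filter and
    rejects common-mode (reference) activity exactly.
    """
    data = np.stack([rec.channel(a) - rec.channel(b) for a, b in pairs])
    labels = [f"{a}-{b}" for a, b in pairs]
    return Recording(labels=labels, fs=rec.fs, data=data, annotations=dict(rec.annotations))


def bandpass(rec: Recording, low: float, high: float, order: int = 4) -> Recording:
    """Zero-phase Butterworth band-pass (applied forward and backward).

    Removes DC and preserves cross-channel phase relations, which the spectral
    model must explain.
    """
    nyq = rec.fs / 2.0
    if not (0 < low < high < nyq):
        raise ValueError(f"band ({low}, {high}) Hz must satisfy 0 < low < high < Nyquist {nyq}")
    sos = scipy.signal.butter(order, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    data = scipy.signal.sosfiltfilt(sos, rec.data, axis=-1)
    return Recording(labels=list(rec.labels), fs=rec.fs, data=data, annotations=dict(rec.annotations))


def segment_windows(duration: float, window_len: float, overlap_frac: float) -> list[tuple[float, float]]:
    """Maximal list of equal-length windows covering ``[0, duration]``.

    Consecutive starts differ by ``window_len * (1 - overlap_frac)``; bounds
    are half-open ``[start, end)`` in seconds from segment start.
    """
    if not 0 <= overlap_frac < 1:
        raise ValueError("overlap fraction must be in [0, 1)")
    if window_len <= 0 or window_len > duration + 1e-12:
        raise ValueError("window length must be positive and fit in the segment")
    step = window_len * (1.0 - overlap_frac)
    out = []
    start = 0.0
    while start + window_len <= duration + 1e-9:
        out.append((start, start + window_len))
        start += step
    return out


@dataclass
class WindowedCSD:
    """Complex cross-spectral matrices indexed by window x frequency x channels."""

    csd: np.ndarray  # (n_windows, n_freqs, n_ch, n_ch) complex
    windows: np.ndarray  # (n_windows, 2) start/end seconds
    grid: FrequencyGrid
    labels: list[str]
    segments: list[str] | None = None  # e.g. 'pre' / 'ictal' per window
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.csd = np.asarray(self.csd, dtype=complex)
        self.windows = np.asarray(self.windows, dtype=float)
        n_w, n_f, n_ch, n_ch2 = self.csd.shape
        if n_ch != n_ch2 or n_f != self.grid.n or self.windows.shape != (n_w, 2):
            raise ValueError("inconsistent CSD container shapes")
        if np.any(np.diff(self.windows[:, 0]) < -1e-12):
            raise ValueError("windows must be time-ordered")

    @property
    def n_windows(self) -> int:
        return self.csd.shape[0]

    @property
    def n_channels(self) -> int:
        return self.csd.shape[2]

    def validate(self, atol: float = 1e-8) -> None:
        if not csd_is_hermitian(self.csd, atol=atol):
            raise ValueError("CSD stack violates Hermitian/positive-diagonal invariants")

    # -- HDF5 round trip ---------------------------------------------------
    def to_hdf5(self, path: str | Path) -> None:
        import h5py

        with h5py.File(path, "w") as h5:
            d = h5.create_dataset("csd", data=self.csd)
            d.attrs["dims"] = "window,frequency,channel_i,channel_j"
            h5.create_dataset("windows", data=self.windows)
            h5.create_dataset("frequencies_hz", data=self.grid.freqs)
            h5.attrs["labels"] = [s.encode() for s in self.labels]
            if self.segments is not None:
                h5.attrs["segments"] = [s.encode() for s in self.segments]
            h5.attrs["meta_yaml"] = yaml.safe_dump(self.meta, sort_keys=True)

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "WindowedCSD":
        import h5py

        with h5py.File(path, "r") as h5:
            segments = None
            if "segments" in h5.attrs:
                segments = [s.decode() if isinstance(s, bytes) else str(s) for s in h5.attrs["segments"]]
            return cls(
                csd=h5["csd"][()],
                windows=h5["windows"][()],
                grid=FrequencyGrid(h5["frequencies_hz"][()]),
                labels=[s.decode() if isinstance(s, bytes) else str(s) for s in h5.attrs["labels"]],
                segments=segments,
                meta=yaml.safe_load(h5.attrs["meta_yaml"]) or {},
            )


def estimate_csd(
    rec: Recording,
    windows: list[tuple[float, float]],
    grid: FrequencyGrid,
    method: str = "var",
    var_order: int = 8,
    n_tapers: int = 5,
    segments: list[str] | None = None,
) -> WindowedCSD:
    """Per-window complex CSD on the grid; Hermitian by construction.

    ``method='var'`` fits a vector autoregression of order ``var_order`` per
    window and evaluates its parametric spectrum; ``method='multitaper'``
    averages DPSS-tapered cross-periodograms and interpolates onto the grid.
    """
    f_lo = grid.freqs[0]
    n_needed = int(np.ceil(rec.fs / f_lo))
    out = []
    for start, end in windows:
        i0, i1 = int(round(start * rec.fs)), int(round(end * rec.fs))
        if i0 < 0 or i1 > rec.data.shape[1]:
            raise ValueError(f"window ({start}, {end}) s outside recording bounds")
        seg = rec.data[:, i0:i1]
        if seg.shape[1] < max(n_needed // 2, 2 * var_order + 2):
            raise ValueError(
                f"window of {seg.shape[1]} samples too short for the {f_lo} Hz "
                "lower bound / estimator order"
            )
        if method == "var":
            S = _var_csd(seg, rec.fs, grid.freqs, var_order)
        elif method == "multitaper":
            S = _multitaper_csd(seg, rec.fs, grid.freqs, n_tapers)
        else:
            raise ValueError(f"unknown estimator {method!r}")
        out.append(0.5 * (S + S.conj().transpose(0, 2, 1)))
    meta = {"estimator": method, "var_order": var_order, "n_tapers": n_tapers}
    return WindowedCSD(
        csd=np.stack(out),
        windows=np.asarray(windows),
        grid=grid,
        labels=list(rec.labels),
        segments=segments,
        meta=meta,
    )


def _var_csd(x: np.ndarray, fs: float, freqs: np.ndarray, order: int) -> np.ndarray:
    """Parametric CSD from a least-squares VAR fit (one-sided density)."""
    n_ch, n = x.shape
    x = x - x.mean(axis=1, keepdims=True)
    Y = x[:, order:].T  # (n-order, n_ch)
    Z = np.hstack([x[:, order - k : n - k].T for k in range(1, order + 1)])
    coef, *_ = np.linalg.lstsq(Z, Y, rcond=None)  # (order*n_ch, n_ch)
    resid = Y - Z @ coef
    sigma = resid.T @ resid / max(resid.shape[0] - coef.shape[0], 1)
    A = coef.T.reshape(n_ch, order, n_ch).transpose(1, 0, 2)  # (order, n_ch, n_ch)
    z = np.exp(-2j * np.pi * freqs[:, None] / fs * np.arange(1, order + 1)[None, :])
    Af = np.eye(n_ch)[None, :, :] - np.einsum("fk,kij->fij", z, A)
    H = np.linalg.inv(Af)
    return 2.0 / fs * (H @ sigma[None, :, :] @ H.conj().transpose(0, 2, 1))


def _multitaper_csd(x: np.ndarray, fs: float, freqs: np.ndarray, n_tapers: int) -> np.ndarray:
    """DPSS multitaper cross-spectral estimate, interpolated onto the grid."""
    n_ch, n = x.shape
    x = x - x.mean(axis=1, keepdims=True)
    nw = (n_tapers + 1) / 2.0
    tapers = scipy.signal.windows.dpss(n, nw, Kmax=n_tapers)  # (K, n), unit energy
    X = np.fft.rfft(tapers[None, :, :] * x[:, None, :], axis=-1)  # (n_ch, K, n_f)
    fgrid = np.fft.rfftfreq(n, 1.0 / fs)
    S_full = 2.0 / (fs * n_tapers) * np.einsum("ikf,jkf->fij", X, X.conj())
    out = np.empty((freqs.size, n_ch, n_ch), dtype=complex)
    for i in range(n_ch):
        for j in range(n_ch):
            out[:, i, j] = np.interp(freqs, fgrid, S_full[:, i, j].real) + 1j * np.interp(
                freqs, fgrid, S_full[:, i, j].imag
            )
    return out
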