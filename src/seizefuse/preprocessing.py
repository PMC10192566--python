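"""Signal conditioning: filter -> normalize -> segment -> (ECG) scalogram.

The pipeline order is fixed.  Filtering is zero-phase (forward-backward)
Butterworth: order-4 band-pass (default 0.1-70 Hz) followed by an order-2
band-stop (default 48-52 Hz) for mains interference.  Min-max scaling maps
each channel of each recording to [0, 1] *before* segmentation, so no
statistic of one recording ever touches another (in particular, held-out
episodes are normalized only from their own data).  Recordings are tiled
with non-overlapping 1-s windows per labeled state interval; a trailing
partial window is dropped.  Each ECG window is expanded into a Mexican-hat
continuous-wavelet scalogram over scales 1..32 with the 1/sqrt(a)
normalization

    WT(a, b) = a^(-1/2) * integral f(t) psi((t - b) / a) dt,

kept as signed coefficients, then average-pooled along time to bound the
2-D network input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .recording import STATE_LABELS, Recording

__all__ = [
    "PreprocessConfig", "EpisodeDataset", "filter_signal", "minmax_normalize",
    "segment_windows", "cwt_scalogram", "mexican_hat", "avgpool_time",
    "build_dataset",
]


@dataclass
class PreprocessConfig:
    low_hz: float = 0.1
    high_hz: float = 70.0
    notch_hz: tuple[float, float] | None = (48.0, 52.0)
    window_s: float = 1.0
    overlap: float = 0.0
    cwt_scales: int = 32
    time_pool: int = 4  # average-pool factor on the scalogram time axis


def design_filters(fs: float, low: float = 0.1, high: float = 70.0,
                   notch: tuple[float, float] | None = (48.0, 52.0)):
    """Butterworth designs: order-4 band-pass and order-2 band-stop (sos)."""
    if fs <= 2 * high:
        raise ValueError(f"fs={fs} must exceed twice the high cutoff {high}")
    sos_bp = sps.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    sos_bs = None
    if notch is not None:
        sos_bs = sps.butter(2, list(notch), btype="bandstop", fs=fs,
                            output="sos")
    return sos_bp, sos_bs


def filter_signal(x: np.ndarray, fs: float, low: float = 0.1,
                  high: float = 70.0,
                  notch: tuple[float, float] | None = (48.0, 52.0)) -> np.ndarray:
    """Zero-phase band-pass (order 4) then optional band-stop (order 2)."""
    sos_bp, sos_bs = design_filters(fs, low, high, notch)
    x = np.asarray(x, dtype=float)
    y = sps.sosfiltfilt(sos_bp, x, axis=-1)
    if sos_bs is not None:
        y = sps.sosfiltfilt(sos_bs, y, axis=-1)
    return y


def minmax_normalize(x: np.ndarray) -> np.ndarray:
    """Map to [0, 1]:  (x - min) / (max - min).

    A constant input has no range; by convention it maps to all zeros
    (with a warning) rather than raising.
    """
    x = np.asarray(x, dtype=float)
    lo, hi = x.min(), x.max()
    if hi - lo == 0:
        warnings.warn("constant input to minmax_normalize; returning zeros",
                      stacklevel=2)
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def segment_windows(recording: Recording, window_s: float = 1.0,
                    overlap: float = 0.0):
    """Tile each state interval with (1-overlap)-hop windows.

    Returns (eeg_windows (n, C, W), ecg_windows (n, W), y (n,), d (n,)).
    Windows never straddle interval boundaries; a trailing remainder is
    dropped.  y is 0 for interictal / 1 for preictal; d is the episode id.
    """
    if not recording.state_intervals:
        raise ValueError("recording has no state_intervals; extract them first")
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    w = int(round(recording.fs * window_s))
    hop = max(int(round(w * (1.0 - overlap))), 1)
    eeg_wins, ecg_wins, ys = [], [], []
    for start, end, state in recording.state_intervals:
        for a in range(start, end - w + 1, hop):
            eeg_wins.append(recording.eeg[:, a:a + w])
            ecg_wins.append(recording.ecg[a:a + w])
            ys.append(STATE_LABELS[state])
    if not eeg_wins:
        warnings.warn("window longer than every interval; no segments",
                      stacklevel=2)
        c = recording.n_eeg_channels
        return (np.empty((0, c, w)), np.empty((0, w)),
                np.empty(0, int), np.empty(0, int))
    y = np.array(ys, dtype=int)
    d = np.full(len(ys), recording.episode_id, dtype=int)
    return np.stack(eeg_wins), np.stack(ecg_wins), y, d


# -- continuous wavelet transform ---------------------------------------------

_MEXH_NORM = 2.0 / (np.sqrt(3.0) * np.pi ** 0.25)


def mexican_hat(t: np.ndarray) -> np.ndarray:
    """Closed-form Mexican-hat (Ricker) mother wavelet, unit L2 norm."""
    return _MEXH_NORM * (1.0 - t ** 2) * np.exp(-0.5 * t ** 2)


def cwt_scalogram(window: np.ndarray, scales=None) -> np.ndarray:
    """Signed Mexican-hat CWT, rows = scales 1..32, columns = time.

    Row a is a^(-1/2) * sum_t f(t) psi((t - b)/a) (unit sample spacing);
    the wavelet is truncated at |t/a| > 8 where it is numerically zero
    (|psi(8)| < 1e-12).
    """
    x = np.asarray(window, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty window")
    if scales is None:
        scales = np.arange(1, 33)
    out = np.empty((len(scales), x.size))
    for i, a in enumerate(scales):
        half = int(np.ceil(8.0 * a))
        t = np.arange(-half, half + 1)
        kernel = mexican_hat(t / a) / np.sqrt(a)
        # psi is even, so correlation equals convolution
        out[i] = sps.fftconvolve(x, kernel, mode="same")
    return out


def avgpool_time(scalogram: np.ndarray, factor: int) -> np.ndarray:
    """Average-pool the last axis by an integer factor (remainder dropped)."""
    if factor <= 1:
        return scalogram
    n = scalogram.shape[-1] // factor
    trimmed = scalogram[..., :n * factor]
    return trimmed.reshape(*scalogram.shape[:-1], n, factor).mean(axis=-1)


# -- dataset assembly ---------------------------------------------------------

@dataclass
class EpisodeDataset:
    """Model-ready labeled segments of one patient.

    eeg : (n, C, W) min-max normalized windows
    ecg : (n, W) min-max normalized raw ECG windows (data-level fusion)
    scalogram : (n, S, Wp) pooled ECG scalograms
    y : (n,) class labels (0 interictal, 1 preictal)
    d : (n,) episode labels
    """

    eeg: np.ndarray
    ecg: np.ndarray
    scalogram: np.ndarray
    y: np.ndarray
    d: np.ndarray
    fs: float
    patient_id: str = "synthetic"
    config: PreprocessConfig = field(default_factory=PreprocessConfig)

    @property
    def n_segments(self) -> int:
        return len(self.y)

    @property
    def episodes(self) -> np.ndarray:
        return np.unique(self.d)

    def subset(self, mask: np.ndarray) -> "EpisodeDataset":
        return EpisodeDataset(self.eeg[mask], self.ecg[mask],
                              self.scalogram[mask], self.y[mask],
                              self.d[mask], self.fs, self.patient_id,
                              self.config)


def build_dataset(recordings: list[Recording],
                  cfg: PreprocessConfig | None = None,
                  patient_id: str = "synthetic") -> EpisodeDataset:
    """Run the full pipeline over a patient's recordings."""
    cfg = cfg or PreprocessConfig()
    eeg_all, ecg_all, scal_all, y_all, d_all = [], [], [], [], []
    fs = recordings[0].fs
    for rec in recordings:
        if rec.fs != fs:
            raise ValueError("all recordings of a patient must share fs")
        filtered_eeg = filter_signal(rec.eeg, rec.fs, cfg.low_hz, cfg.high_hz,
                                     cfg.notch_hz)
        filtered_ecg = filter_signal(rec.ecg, rec.fs, cfg.low_hz, cfg.high_hz,
                                     cfg.notch_hz)
        norm_eeg = np.stack([minmax_normalize(ch) for ch in filtered_eeg])
        norm_ecg = minmax_normalize(filtered_ecg)
        conditioned = Recording(norm_eeg, norm_ecg, rec.fs, rec.episode_id,
                                list(rec.state_intervals), dict(rec.metadata))
        eeg_w, ecg_w, y, d = segment_windows(conditioned, cfg.window_s,
                                             cfg.overlap)
        scales = np.arange(1, cfg.cwt_scales + 1)
        scal = np.stack([avgpool_time(cwt_scalogram(w, scales), cfg.time_pool)
                         for w in ecg_w]) if len(ecg_w) else np.empty((0, cfg.cwt_scales, 0))
        eeg_all.append(eeg_w)
        ecg_all.append(ecg_w)
        scal_all.append(scal)
        y_all.append(y)
        d_all.append(d)
    return EpisodeDataset(np.concatenate(eeg_all), np.concatenate(ecg_all),
                          np.concatenate(scal_all), np.concatenate(y_all),
                          np.concatenate(d_all), fs, patient_id, cfg)
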