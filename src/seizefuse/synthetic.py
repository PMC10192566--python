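"""Synthetic multimodal patient generator.

Emulates the statistical structure the prediction method assumes, without
claiming physiological realism:

* several *episodes* per patient whose marginal distributions differ
  (a spectral/amplitude shift between episodes — the reason for
  episode-adversarial training), and
* class-dependent, partially complementary signal: the preictal state adds
  narrow-band EEG power and shortens the ECG inter-beat interval.

EEG channels are band-limited Gaussian noise; the ECG is a quasi-periodic
train of Gaussian bumps.  Each episode holds one contiguous interictal
block followed by one preictal block of equal length.

All frequencies are expressed as fractions of the sampling rate so that a
scaled-down patient (low fs, short blocks) has the same qualitative
structure as a full-scale one.  One seed stream per patient is spawned
into independent per-episode substreams, so adding episodes never changes
earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .recording import INTERICTAL, PREICTAL, Recording

__all__ = ["SyntheticSpec", "generate_patient"]

# relative band placement (fractions of fs); all below 0.13*fs so the
# class/episode structure survives the 0.1-70 Hz analysis band at 512 Hz
_BASE_BAND = 0.12          # broadband EEG background: lowpass cutoff
_EPISODE_BAND_LO = 0.04    # episode-specific narrow band, lower center bound
_EPISODE_BAND_HI = 0.08    # upper center bound
_PREICTAL_BAND = 0.11      # preictal narrow band center
_SHIFT_BAND = 0.09         # episode-baseline band, adjacent to the preictal one
_BAND_HALFWIDTH = 0.01

_RR_BASE_S = 0.8           # baseline inter-beat interval (75 bpm)
_QRS_SIGMA_S = 0.03        # Gaussian bump width


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic patient.

    Defaults mirror the real-data setting the method targets: 512 Hz scalp
    recordings with 29 EEG channels plus one ECG channel, at least three
    episodes, and 5-minute (300 s) preictal/interictal blocks.
    """

    n_episodes: int = 3
    seg_seconds_per_state: float = 300.0
    fs: float = 512.0
    n_eeg_channels: int = 29
    episode_shift: float = 1.0
    eeg_effect: float = 1.0
    ecg_effect: float = 0.5
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_episodes < 1:
            raise ValueError("n_episodes must be >= 1")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.seg_seconds_per_state <= 0:
            raise ValueError("seg_seconds_per_state must be positive")
        if self.n_eeg_channels < 1:
            raise ValueError("n_eeg_channels must be >= 1")
        for name in ("episode_shift", "eeg_effect", "ecg_effect", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def _band_noise(rng: np.random.Generator, n: int, center: float,
                halfwidth: float) -> np.ndarray:
    """Unit-variance Gaussian noise band-passed around `center` (x fs)."""
    lo = max(center - halfwidth, 1e-3)
    hi = min(center + halfwidth, 0.499)
    sos = sps.butter(2, [2 * lo, 2 * hi], btype="bandpass", output="sos")
    x = sps.sosfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def _broadband(rng: np.random.Generator, n: int) -> np.ndarray:
    sos = sps.butter(4, 2 * _BASE_BAND, btype="lowpass", output="sos")
    x = sps.sosfilt(sos, rng.standard_normal(n))
    return x / x.std()


def _ecg_trace(rng: np.random.Generator, n: int, fs: float, rr_mean_s: float,
               rr_sd_s: float) -> np.ndarray:
    t_beat = 0.0
    beats = []
    while t_beat < n / fs:
        beats.append(t_beat)
        rr = rr_mean_s + rng.normal(0.0, rr_sd_s)
        t_beat += max(rr, 0.2)  # refractory floor
    x = np.zeros(n)
    half = int(round(4 * _QRS_SIGMA_S * fs))
    for tb in beats:
        c = int(round(tb * fs))
        a, b = max(c - half, 0), min(c + half + 1, n)
        if a >= b:
            continue
        tt = (np.arange(a, b) / fs) - tb
        x[a:b] += np.exp(-0.5 * (tt / _QRS_SIGMA_S) ** 2)
    return x


def _make_episode(spec: SyntheticSpec, episode_id: int,
                  rng: np.random.Generator) -> Recording:
    fs = spec.fs
    n_state = int(round(spec.seg_seconds_per_state * fs))
    n = 2 * n_state
    pre = slice(n_state, n)  # interictal block first, then preictal

    # episode signature, scaled by episode_shift: (a) an episode-specific
    # baseline power level in a narrow band spectrally adjacent to the
    # preictal band — coarse spectral features mix the two, so a
    # classifier that leans on overall power around the preictal band
    # miscalibrates on an unseen episode, while the pure preictal band
    # remains an episode-invariant cue — plus (b) a narrow band at an
    # episode-specific center frequency and a mild global gain
    f_ep = _EPISODE_BAND_LO + (_EPISODE_BAND_HI - _EPISODE_BAND_LO) * rng.uniform()
    gain_ep = float(np.exp(0.1 * spec.episode_shift * rng.normal()))
    # baseline levels cycle through a fixed low/mid/high ladder so
    # consecutive episodes are guaranteed to differ (episode_id-keyed,
    # hence unaffected by adding later episodes)
    baseline_adjacent = spec.episode_shift * (0.2 + 0.5 * (episode_id % 3))

    eeg = np.empty((spec.n_eeg_channels, n))
    ch_gain_pre = rng.uniform(0.5, 1.5, spec.n_eeg_channels)
    for ch in range(spec.n_eeg_channels):
        x = _broadband(rng, n)
        x += spec.episode_shift * _band_noise(rng, n, f_ep, _BAND_HALFWIDTH)
        x += baseline_adjacent * _band_noise(rng, n, _SHIFT_BAND,
                                             _BAND_HALFWIDTH)
        x *= gain_ep
        x[pre] += (spec.eeg_effect * ch_gain_pre[ch]
                   * _band_noise(rng, n_state, _PREICTAL_BAND, _BAND_HALFWIDTH))
        x += spec.noise_sd * 0.5 * rng.standard_normal(n)
        eeg[ch] = 20.0 * x  # microvolt-like scale

    rr_base = _RR_BASE_S * float(
        np.exp(0.08 * spec.episode_shift * ((episode_id % 3) - 1)))
    rr_pre = rr_base / (1.0 + 0.5 * spec.ecg_effect)
    rr_sd = 0.05 * spec.noise_sd * _RR_BASE_S
    ecg = np.concatenate([
        _ecg_trace(rng, n_state, fs, rr_base, rr_sd),
        _ecg_trace(rng, n_state, fs, rr_pre, rr_sd),
    ])
    ecg += spec.noise_sd * 0.05 * rng.standard_normal(n)

    return Recording(
        eeg=eeg,
        ecg=ecg,
        fs=fs,
        episode_id=episode_id,
        state_intervals=[(0, n_state, INTERICTAL), (n_state, n, PREICTAL)],
        metadata={"synthetic": True, "seed": spec.seed,
                  "episode_band_center_rel": f_ep},
    )


def generate_patient(spec: SyntheticSpec) -> list[Recording]:
    """Generate one recording per episode; deterministic under spec.seed."""
    spec.validate()
    children = np.random.SeedSequence(spec.seed).spawn(spec.n_episodes)
    return [
        _make_episode(spec, ep, np.random.default_rng(child))
        for ep, child in enumerate(children)
    ]
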