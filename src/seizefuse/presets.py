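"""Canonical experiment presets.

``full_scale`` mirrors the real-data setting the method targets (512 Hz,
29 EEG channels, 5-minute state blocks, 100 epochs, batch 128, Adam
1e-3).  ``scaled`` is the CPU-scale counterpart used by the test-bench
experiments: the same pipeline and statistical structure at 64 Hz with 4
EEG channels, 40-second state blocks, reduced layer widths, 20 epochs and
a proportionally higher learning rate, with the analysis band narrowed to
0.1-28 Hz (the mains notch does not apply below a 32 Hz Nyquist).  Four
samples per LSTM step keep the recurrent pass tractable at this scale.

Effect sizes for ``scaled`` were calibrated once on the synthetic
generator: ``eeg_effect=2.5, ecg_effect=2.5`` give single-branch
held-out accuracy well above chance within 20 epochs, and
``episode_shift=2.5`` produces a between-episode covariate shift strong
enough that episode-invariant training has measurable headroom.
"""

from __future__ import annotations

from dataclasses import replace

from .networks import BranchConfig
from .preprocessing import PreprocessConfig
from .synthetic import SyntheticSpec
from .training import TrainConfig

__all__ = ["scaled_synthetic_spec", "scaled_preprocess", "scaled_branch",
           "scaled_train", "full_scale_train"]


def scaled_synthetic_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    spec = SyntheticSpec(
        n_episodes=3, seg_seconds_per_state=40.0, fs=64.0, n_eeg_channels=4,
        episode_shift=2.5, eeg_effect=2.5, ecg_effect=2.5, noise_sd=1.0,
        seed=seed)
    return replace(spec, **overrides) if overrides else spec


def scaled_preprocess(**overrides) -> PreprocessConfig:
    cfg = PreprocessConfig(low_hz=0.1, high_hz=28.0, notch_hz=None,
                           window_s=1.0, overlap=0.0, cwt_scales=32,
                           time_pool=4)
    return replace(cfg, **overrides) if overrides else cfg


def scaled_branch(**overrides) -> BranchConfig:
    cfg = BranchConfig(lstm_hidden=8, conv1d_channels=(8, 8, 8, 8),
                       conv2d_channels=(4, 4, 8, 8, 8), fc_sizes=(16, 2),
                       feature_dim=16, dropout=0.0, time_patch=4)
    return replace(cfg, **overrides) if overrides else cfg


def scaled_train(seed: int = 0, **overrides) -> TrainConfig:
    cfg = TrainConfig(epochs=20, batch_size=16, lr=0.003, seed=seed)
    return replace(cfg, **overrides) if overrides else cfg


def full_scale_train(seed: int = 0, **overrides) -> TrainConfig:
    cfg = TrainConfig(epochs=100, batch_size=128, lr=0.001, seed=seed)
    return replace(cfg, **overrides) if overrides else cfg
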