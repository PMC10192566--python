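"""The two modality branches, classifier heads and episode discriminators.

EEG branch (feature extractor G_f1): a bidirectional LSTM reads the window
sample by sample (each step sees the vector of channel values), its
sequence output feeds a four-layer 1-D convolutional stack with max
pooling, and a linear projection yields the feature vector.  ECG branch
(G_f2): the wavelet scalogram is treated as a one-channel image through a
five-layer 2-D convolutional stack with pooling, then projected to the
same feature dimension.  Category classifiers (G_c1/G_c2) and episode
discriminators (G_d) are two-layer fully connected heads emitting
row-normalized probabilities.  The gradient-reversal connector between
extractor and discriminator lives in :mod:`seizefuse.autodiff`.

Layer widths, kernel sizes and activations are configuration, not
architecture: every width can be shrunk for CPU-scale experiments without
changing the wiring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, gradient_reversal, softmax
from . import nnet
from .nnet import BiLSTM, Conv1d, Conv2d, Dropout, Linear, MaxPool1d, MaxPool2d, Module

__all__ = [
    "BranchConfig", "EEGFeatureExtractor", "ECGFeatureExtractor", "Head",
    "build_eeg_branch", "build_ecg_branch", "build_discriminator",
    "gradient_reversal",
]


@dataclass
class BranchConfig:
    lstm_hidden: int = 64
    lstm_bidirectional: bool = True
    conv1d_channels: tuple = (32, 32, 64, 64)
    conv2d_channels: tuple = (8, 16, 16, 32, 32)
    fc_sizes: tuple = (64, 2)          # (hidden width, n_classes)
    feature_dim: int = 128
    n_classes: int = 2
    n_episode_classes: int | None = None  # set per cross-validation fold
    grl_on: bool = True
    dropout: float = 0.2
    kernel: int = 3
    time_patch: int = 1  # samples grouped per LSTM step (1 = one sample/step)

    def validate(self) -> None:
        if len(self.conv1d_channels) != 4:
            raise ValueError("conv1d_channels must have exactly 4 layers")
        if len(self.conv2d_channels) != 5:
            raise ValueError("conv2d_channels must have exactly 5 layers")
        if len(self.fc_sizes) != 2:
            raise ValueError("fc_sizes must name exactly 2 layers")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")


def _check_shape(name: str, got: tuple, expected: str) -> None:
    raise ValueError(f"{name}: expected input shaped {expected}, got {got}")


class Head(Module):
    """Two fully connected layers ending in a softmax over classes."""

    def __init__(self, n_in: int, n_hidden: int, n_out: int,
                 rng: np.random.Generator, dropout: float = 0.0):
        self.fc1 = Linear(n_in, n_hidden, rng)
        self.drop = Dropout(dropout, rng)
        self.fc2 = Linear(n_hidden, n_out, rng)

    def forward(self, f: Tensor) -> Tensor:
        return softmax(self.fc2(self.drop(self.fc1(f).relu())))


class EEGFeatureExtractor(Module):
    def __init__(self, cfg: BranchConfig, n_channels: int, window: int,
                 rng: np.random.Generator):
        cfg.validate()
        if window % cfg.time_patch:
            raise ValueError("time_patch must divide the window length")
        self.cfg = cfg
        self.n_channels = n_channels
        self.window = window
        step_in = n_channels * cfg.time_patch
        self.lstm = BiLSTM(step_in, cfg.lstm_hidden, rng) \
            if cfg.lstm_bidirectional else nnet.LSTM(step_in, cfg.lstm_hidden, rng)
        seq_dim = cfg.lstm_hidden * (2 if cfg.lstm_bidirectional else 1)
        chans = [seq_dim, *cfg.conv1d_channels]
        self.convs = [Conv1d(a, b, cfg.kernel, rng) for a, b in zip(chans, chans[1:])]
        self.pool = MaxPool1d(2)
        length = window // cfg.time_patch
        for _ in cfg.conv1d_channels:
            length = max(length // 2, 1)
        self.proj = Linear(cfg.conv1d_channels[-1] * length, cfg.feature_dim, rng)
        self.drop = Dropout(cfg.dropout, rng)

    def forward(self, x: Tensor) -> Tensor:
        B, C, W = x.data.shape
        if C != self.n_channels or W != self.window:
            _check_shape("EEG branch", (B, C, W),
                         f"(batch, {self.n_channels}, {self.window})")
        tp = self.cfg.time_patch
        # min-max-normalized inputs live in [0,1]; center and expand to
        # [-2,2] so the recurrent units start in their responsive range
        x = (x - 0.5) * 4.0
        # (B, C, W) -> time-major steps of channel(-patch) vectors
        steps = x.reshape(B, C, W // tp, tp).transpose(2, 0, 1, 3).reshape(
            W // tp, B, C * tp)
        seq = self.lstm(steps)                     # (T, B, seq_dim)
        h = seq.transpose(1, 2, 0)                 # (B, seq_dim, T)
        for conv in self.convs:
            h = self.pool(conv(h).relu())
        h = h.reshape(B, h.data.shape[1] * h.data.shape[2])
        return self.drop(self.proj(h).relu())


class ECGFeatureExtractor(Module):
    def __init__(self, cfg: BranchConfig, n_scales: int, width: int,
                 rng: np.random.Generator):
        cfg.validate()
        self.cfg = cfg
        self.n_scales = n_scales
        self.width = width
        chans = [1, *cfg.conv2d_channels]
        self.convs = [Conv2d(a, b, cfg.kernel, rng) for a, b in zip(chans, chans[1:])]
        self.pool = MaxPool2d(2)
        h, w = n_scales, width
        for _ in cfg.conv2d_channels:
            h, w = max(h // 2, 1), max(w // 2, 1)
        self.proj = Linear(cfg.conv2d_channels[-1] * h * w, cfg.feature_dim, rng)
        self.drop = Dropout(cfg.dropout, rng)

    def forward(self, x: Tensor) -> Tensor:
        if x.data.ndim == 3:  # (B, S, W) -> 1-channel image
            x = x.reshape(x.data.shape[0], 1, *x.data.shape[1:])
        B, _, S, W = x.data.shape
        if S != self.n_scales or W != self.width:
            _check_shape("ECG branch", (B, 1, S, W),
                         f"(batch, 1, {self.n_scales}, {self.width})")
        # standardize each scalogram (fixed, parameter-free) so the conv
        # stack starts from a well-conditioned input regardless of the
        # wavelet coefficient magnitudes
        mu = x.data.mean(axis=(1, 2, 3), keepdims=True)
        sd = x.data.std(axis=(1, 2, 3), keepdims=True) + 1e-8
        h = (x - mu) * (1.0 / sd)
        for conv in self.convs:
            h = self.pool(conv(h).relu())
        h = h.reshape(B, h.data.shape[1] * h.data.shape[2] * h.data.shape[3])
        return self.drop(self.proj(h).relu())


def build_eeg_branch(cfg: BranchConfig, n_channels: int, window: int,
                     rng: np.random.Generator):
    """Returns (feature extractor G_f1, classifier head G_c1)."""
    extractor = EEGFeatureExtractor(cfg, n_channels, window, rng)
    head = Head(cfg.feature_dim, cfg.fc_sizes[0], cfg.n_classes, rng, cfg.dropout)
    return extractor, head


def build_ecg_branch(cfg: BranchConfig, n_scales: int, width: int,
                     rng: np.random.Generator):
    """Returns (feature extractor G_f2, classifier head G_c2)."""
    extractor = ECGFeatureExtractor(cfg, n_scales, width, rng)
    head = Head(cfg.feature_dim, cfg.fc_sizes[0], cfg.n_classes, rng, cfg.dropout)
    return extractor, head


def build_discriminator(cfg: BranchConfig, rng: np.random.Generator,
                        n_in: int | None = None) -> Head:
    """Episode discriminator G_d: feature_dim -> n_episode_classes."""
    if cfg.n_episode_classes is None:
        raise ValueError("cfg.n_episode_classes must be set for discriminators")
    return Head(n_in or cfg.feature_dim, cfg.fc_sizes[0],
                cfg.n_episode_classes, rng, cfg.dropout)


def parameter_count(module: Module) -> int:
    return sum(p.data.size for p in module.parameters())
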