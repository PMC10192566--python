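"""Multimodal fusion: decision-level weighting plus two ablation modes.

The primary strategy fuses the two branches' class-probability outputs by
a weighted average whose weights are driven by each branch's
classification error rate:

    w_i = 1 + arctan((1 - err_i) / err_i),      W_i = w_i / (w_1 + w_2)

so the more reliable branch dominates while the weaker one still
contributes.  Data-level fusion (stack the ECG trace as a 30th "channel"
and use one EEG-type branch) and feature-level fusion (concatenate the two
feature vectors before a single classifier head) are kept as comparison
modes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FusionWeights", "dynamic_weights", "fixed_weights", "fuse_decisions",
    "fuse_data_level", "fuse_feature_level", "predict_classes",
]


@dataclass(frozen=True)
class FusionWeights:
    err1: float
    err2: float
    w1: float
    w2: float
    W1: float
    W2: float


def dynamic_weights(err1: float, err2: float, eps: float = 1e-6) -> FusionWeights:
    """Error-rate-driven branch weights (arctan in radians).

    Error rates must lie in [0, 1]; values below `eps` are clamped to keep
    the arctan argument finite without disturbing the ordering.
    """
    for name, e in (("err1", err1), ("err2", err2)):
        if not 0.0 <= e <= 1.0:
            raise ValueError(f"{name}={e} outside [0, 1]")
    e1, e2 = max(err1, eps), max(err2, eps)
    w1 = 1.0 + np.arctan((1.0 - e1) / e1)
    w2 = 1.0 + np.arctan((1.0 - e2) / e2)
    total = w1 + w2
    return FusionWeights(err1, err2, float(w1), float(w2),
                         float(w1 / total), float(w2 / total))


def fixed_weights() -> FusionWeights:
    """The fixed 0.5/0.5 ablation setting."""
    return FusionWeights(np.nan, np.nan, 1.0, 1.0, 0.5, 0.5)


def fuse_decisions(p_eeg: np.ndarray, p_ecg: np.ndarray,
                   weights: FusionWeights) -> np.ndarray:
    """Convex combination of aligned probability batches."""
    p_eeg = np.asarray(p_eeg, dtype=float)
    p_ecg = np.asarray(p_ecg, dtype=float)
    if p_eeg.shape != p_ecg.shape:
        raise ValueError(
            f"branch outputs misaligned: {p_eeg.shape} vs {p_ecg.shape}")
    return weights.W1 * p_eeg + weights.W2 * p_ecg


def predict_classes(probs: np.ndarray) -> np.ndarray:
    """Argmax over classes; exact ties resolve to class 0 (interictal)."""
    return np.argmax(probs, axis=-1)


def fuse_data_level(eeg_window: np.ndarray, ecg_window: np.ndarray,
                    fs_eeg: float | None = None,
                    fs_ecg: float | None = None) -> np.ndarray:
    """Stack the ECG trace under the EEG channels (single-branch input).

    The modalities must share the sampling rate and be time aligned
    (equal sample counts).
    """
    if fs_eeg is not None and fs_ecg is not None and fs_eeg != fs_ecg:
        raise ValueError(f"sampling rates differ: {fs_eeg} vs {fs_ecg}")
    eeg = np.atleast_2d(np.asarray(eeg_window, dtype=float))
    ecg = np.asarray(ecg_window, dtype=float).ravel()
    if eeg.shape[-1] != ecg.shape[-1]:
        raise ValueError(
            f"time misalignment: eeg has {eeg.shape[-1]} samples, "
            f"ecg has {ecg.shape[-1]}")
    return np.vstack([eeg, ecg[None, :]])


def fuse_feature_level(f_eeg: np.ndarray, f_ecg: np.ndarray) -> np.ndarray:
    """Concatenate branch feature vectors, EEG features first."""
    return np.concatenate([np.asarray(f_eeg, dtype=float),
                           np.asarray(f_ecg, dtype=float)], axis=-1)
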