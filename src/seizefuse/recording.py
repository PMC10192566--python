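"""Core containers for multimodal (EEG + ECG) recordings."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

INTERICTAL = "interictal"
PREICTAL = "preictal"
STATES = (INTERICTAL, PREICTAL)

#: class labels: interictal segments are the negative class, preictal the positive
STATE_LABELS = {INTERICTAL: 0, PREICTAL: 1}


@dataclass
class Recording:
    """One episode's raw signals.

    eeg : (n_channels, n_samples) array, microvolt-like units
    ecg : (n_samples,) array
    state_intervals : half-open, 0-based sample intervals
        ``(start, end, state)`` with state in {"interictal", "preictal"};
        disjoint, sorted, within range.
    """

    eeg: np.ndarray
    ecg: np.ndarray
    fs: float
    episode_id: int
    state_intervals: list[tuple[int, int, str]] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.eeg = np.atleast_2d(np.asarray(self.eeg, dtype=float))
        self.ecg = np.asarray(self.ecg, dtype=float).ravel()
        if self.eeg.shape[1] != self.ecg.shape[0]:
            raise ValueError(
                f"eeg has {self.eeg.shape[1]} samples but ecg has "
                f"{self.ecg.shape[0]}; modalities must be time aligned"
            )
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        self.validate_intervals()

    @property
    def n_samples(self) -> int:
        return self.eeg.shape[1]

    @property
    def n_eeg_channels(self) -> int:
        return self.eeg.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def validate_intervals(self) -> None:
        prev_end = 0
        for start, end, state in self.state_intervals:
            if state not in STATES:
                raise ValueError(f"unknown interval state {state!r}")
            if not (0 <= start < end <= self.n_samples):
                raise ValueError(
                    f"interval [{start}, {end}) outside record of "
                    f"{self.n_samples} samples"
                )
            if start < prev_end:
                raise ValueError("state intervals overlap or are unsorted")
            prev_end = end
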