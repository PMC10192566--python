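"""EDF input/output and seizure-annotation handling.

Reading goes through :func:`mne.io.read_raw_edf`.  Writing uses a minimal
EDF encoder (256-byte ASCII headers + little-endian int16 data records,
one-second records) sufficient for the synthetic recordings, so the
synthetic path exercises exactly the same reader as real data.

Annotations are a plain JSON/CSV sidecar of seizure onsets/offsets plus a
channel-role map; :func:`extract_state_intervals` turns them into labeled
preictal/interictal sample intervals.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .recording import INTERICTAL, PREICTAL, Recording

__all__ = [
    "AnnotationSet", "write_edf", "write_patient", "read_patient",
    "load_recording", "extract_state_intervals",
]


@dataclass
class AnnotationSet:
    """Seizure times (seconds from record start) and channel roles."""

    seizure_onsets: list[float]
    seizure_offsets: list[float]
    channel_roles: dict[str, str] = field(default_factory=dict)  # name -> eeg|ecg|drop

    def __post_init__(self):
        if len(self.seizure_onsets) != len(self.seizure_offsets):
            raise ValueError("onsets and offsets must have equal length")
        if any(b <= a for a, b in zip(self.seizure_onsets, self.seizure_offsets)):
            raise ValueError("every offset must exceed its onset")
        if any(b >= a for a, b in zip(self.seizure_onsets[1:], self.seizure_onsets)):
            raise ValueError("onsets must be strictly increasing")
        roles = set(self.channel_roles.values())
        if not roles <= {"eeg", "ecg", "drop"}:
            raise ValueError(f"unknown channel role in {roles}")

    @classmethod
    def from_file(cls, path: str | Path, channel_roles: dict[str, str] | None = None):
        path = Path(path)
        if path.suffix == ".json":
            obj = json.loads(path.read_text())
            return cls(obj["onset_s"], obj["offset_s"],
                       channel_roles or obj.get("channel_roles", {}))
        with open(path) as fh:
            rows = list(csv.DictReader(fh))
        return cls([float(r["onset_s"]) for r in rows],
                   [float(r["offset_s"]) for r in rows], channel_roles or {})


# -- EDF writing --------------------------------------------------------------

def _field(value, width: int) -> bytes:
    b = str(value).encode("ascii")[:width]
    return b + b" " * (width - len(b))


def write_edf(path: str | Path, signals: np.ndarray, fs: int,
              labels: list[str]) -> None:
    """Write (n_signals, n_samples) float data as a 16-bit EDF file.

    Record duration is 1 s, so `fs` must be an integer; a trailing partial
    record is dropped.  Physical range is the per-channel data range.
    """
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    fs = int(fs)
    ns, n = signals.shape
    if len(labels) != ns:
        raise ValueError("one label per signal required")
    n_rec = n // fs
    pmin = signals.min(axis=1)
    pmax = signals.max(axis=1)
    pmin = np.where(pmax - pmin < 1e-9, pmin - 1.0, pmin)
    pmin = np.array([float(f"{v:.6g}") for v in pmin])
    pmax = np.array([float(f"{v:.6g}") for v in pmax])

    hdr = b""
    hdr += _field(0, 8) + _field("X X X X", 80) + _field("Startdate X X X X", 80)
    hdr += _field("01.01.00", 8) + _field("00.00.00", 8)
    hdr += _field(256 * (ns + 1), 8) + _field("", 44)
    hdr += _field(n_rec, 8) + _field(1, 8) + _field(ns, 4)
    for lab in labels:
        hdr += _field(lab, 16)
    hdr += _field("", 80) * ns + _field("uV", 8) * ns
    for v in pmin:
        hdr += _field(f"{v:.6g}", 8)
    for v in pmax:
        hdr += _field(f"{v:.6g}", 8)
    hdr += _field(-32768, 8) * ns + _field(32767, 8) * ns
    hdr += _field("", 80) * ns + _field(fs, 8) * ns + _field("", 32) * ns

    scale = (pmax - pmin) / 65535.0
    digital = np.round((signals - pmin[:, None]) / scale[:, None]) - 32768.0
    digital = np.clip(digital, -32768, 32767).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(hdr)
        for r in range(n_rec):
            for s in range(ns):
                fh.write(digital[s, r * fs:(r + 1) * fs].tobytes())


def write_patient(recordings: list[Recording], out_dir: str | Path) -> list[Path]:
    """Persist one EDF + JSON sidecar per episode; returns the EDF paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for rec in recordings:
        labels = [f"EEG ch{c + 1:02d}" for c in range(rec.n_eeg_channels)] + ["ECG"]
        stem = f"episode_{rec.episode_id:02d}"
        edf_path = out_dir / f"{stem}.edf"
        write_edf(edf_path, np.vstack([rec.eeg, rec.ecg[None, :]]),
                  int(rec.fs), labels)
        sidecar = {
            "episode_id": rec.episode_id,
            "fs": rec.fs,
            "channel_roles": {lab: ("ecg" if lab == "ECG" else "eeg")
                              for lab in labels},
            "state_intervals": [[a, b, s] for a, b, s in rec.state_intervals],
        }
        (out_dir / f"{stem}.json").write_text(json.dumps(sidecar, indent=1))
        paths.append(edf_path)
    return paths


# -- EDF reading --------------------------------------------------------------

def load_recording(edf_path: str | Path, channel_roles: dict[str, str],
                   episode_id: int = 0) -> Recording:
    """Read an EDF file and split channels into EEG matrix + ECG vector.

    EEG channels keep the order in which they appear in `channel_roles`;
    channels marked ``drop`` are excluded.  Raises if a named channel is
    missing or exactly one ECG channel is not present.
    """
    import mne

    raw = mne.io.read_raw_edf(str(edf_path), preload=True, verbose="error")
    present = set(raw.ch_names)
    missing = [name for name in channel_roles if name not in present]
    if missing:
        raise ValueError(f"channels named in roles but absent from EDF: {missing}")
    eeg_names = [n for n, r in channel_roles.items() if r == "eeg"]
    ecg_names = [n for n, r in channel_roles.items() if r == "ecg"]
    if not eeg_names or len(ecg_names) != 1:
        raise ValueError(
            f"need >=1 eeg and exactly 1 ecg channel, got "
            f"{len(eeg_names)} eeg / {len(ecg_names)} ecg"
        )
    data = raw.get_data(picks=eeg_names + ecg_names) * 1e6  # Volt -> uV
    return Recording(
        eeg=data[:-1],
        ecg=data[-1],
        fs=float(raw.info["sfreq"]),
        episode_id=episode_id,
        metadata={"source": str(edf_path), "eeg_channels": eeg_names,
                  "ecg_channel": ecg_names[0]},
    )


def read_patient(data_dir: str | Path) -> list[Recording]:
    """Read back a directory written by :func:`write_patient`."""
    data_dir = Path(data_dir)
    recordings = []
    for sidecar_path in sorted(data_dir.glob("episode_*.json")):
        meta = json.loads(sidecar_path.read_text())
        rec = load_recording(sidecar_path.with_suffix(".edf"),
                             meta["channel_roles"], meta["episode_id"])
        rec.state_intervals = [(int(a), int(b), s)
                               for a, b, s in meta["state_intervals"]]
        rec.validate_intervals()
        recordings.append(rec)
    if not recordings:
        raise FileNotFoundError(f"no episode_*.json sidecars under {data_dir}")
    return recordings


# -- state-interval extraction ------------------------------------------------

def extract_state_intervals(recording: Recording, annotations: AnnotationSet,
                            preictal_s: float = 300.0,
                            min_interictal_s: float = 300.0,
                            interictal_gap_s: float = 1800.0) -> Recording:
    """Label preictal and interictal sample intervals from seizure times.

    For each onset t the preictal interval is [t - preictal_s, t); an onset
    closer than preictal_s to the record start is skipped with a warning
    (counted in ``metadata["skipped_preictal"]``).  Interictal intervals
    are the maximal spans lying at least `interictal_gap_s` from every
    seizure interval (the same buffer serves as postictal exclusion) and
    from every preictal span; spans shorter than `min_interictal_s` are
    discarded.
    """
    if preictal_s <= 0:
        raise ValueError("preictal_s must be positive")
    fs = recording.fs
    n = recording.n_samples

    preictal, skipped = [], 0
    for onset in annotations.seizure_onsets:
        start = onset - preictal_s
        if start < 0:
            skipped += 1
            warnings.warn(
                f"onset at {onset:.1f}s closer than {preictal_s:.0f}s to "
                "record start; episode skipped", stacklevel=2)
            continue
        a, b = int(round(start * fs)), int(round(onset * fs))
        preictal.append((a, min(b, n)))

    # exclusion zones: seizures and preictal spans, each padded by the gap
    gap = int(round(interictal_gap_s * fs))
    zones = []
    for onset, offset in zip(annotations.seizure_onsets, annotations.seizure_offsets):
        a, b = int(round(onset * fs)), int(round(offset * fs))
        zones.append((max(a - gap, 0), min(b + gap, n)))
    zones += [(max(a - gap, 0), min(b + gap, n)) for a, b in preictal]
    zones.sort()

    interictal, cursor = [], 0
    min_len = int(round(min_interictal_s * fs))
    for a, b in zones + [(n, n)]:
        if a - cursor >= min_len:
            interictal.append((cursor, a))
        cursor = max(cursor, b)

    intervals = ([(a, b, PREICTAL) for a, b in preictal]
                 + [(a, b, INTERICTAL) for a, b in interictal])
    intervals.sort()
    recording.state_intervals = intervals
    recording.metadata["skipped_preictal"] = skipped
    recording.validate_intervals()
    return recording
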