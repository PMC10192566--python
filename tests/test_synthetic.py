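"""Properties of the synthetic patient generator."""

import dataclasses

import numpy as np
import pytest
from scipy import signal as sps
from sklearn.metrics import roc_auc_score

from seizefuse import SyntheticSpec, generate_patient
from seizefuse.recording import INTERICTAL, PREICTAL


def small_spec(**kw):
    base = dict(n_episodes=3, seg_seconds_per_state=30.0, fs=64.0,
                n_eeg_channels=2, episode_shift=1.0, eeg_effect=1.0,
                ecg_effect=1.0, noise_sd=1.0, seed=7)
    base.update(kw)
    return SyntheticSpec(**base)


def bandpower_per_window(rec, lo_rel, hi_rel, win_s=4.0):
    """Mean EEG power in a relative band, one value per window, with labels."""
    w = int(rec.fs * win_s)
    vals, labels = [], []
    for start, end, state in rec.state_intervals:
        for a in range(start, end - w + 1, w):
            fseg, pseg = sps.periodogram(rec.eeg[:, a:a + w], fs=rec.fs, axis=-1)
            band = (fseg >= lo_rel * rec.fs) & (fseg <= hi_rel * rec.fs)
            vals.append(pseg[:, band].mean())
            labels.append(1 if state == PREICTAL else 0)
    return np.array(vals), np.array(labels)


def test_identical_spec_gives_byte_identical_output():
    a = generate_patient(small_spec())
    b = generate_patient(small_spec())
    for ra, rb in zip(a, b):
        assert np.array_equal(ra.eeg, rb.eeg)
        assert np.array_equal(ra.ecg, rb.ecg)
        assert ra.state_intervals == rb.state_intervals


def test_adding_episodes_preserves_earlier_ones():
    three = generate_patient(small_spec(n_episodes=3))
    five = generate_patient(small_spec(n_episodes=5))
    for r3, r5 in zip(three, five):
        assert np.array_equal(r3.eeg, r5.eeg)


def test_episode_structure():
    recs = generate_patient(small_spec())
    assert len(recs) == 3
    n_state = int(30.0 * 64)
    for ep, rec in enumerate(recs):
        assert rec.episode_id == ep
        assert rec.state_intervals == [(0, n_state, INTERICTAL),
                                       (n_state, 2 * n_state, PREICTAL)]
        assert rec.eeg.shape == (2, 2 * n_state)
        assert rec.ecg.shape == (2 * n_state,)


@pytest.mark.parametrize("field,value", [
    ("n_episodes", 0), ("fs", 0), ("seg_seconds_per_state", -1.0),
    ("n_eeg_channels", 0), ("episode_shift", -0.1), ("eeg_effect", -1.0),
    ("ecg_effect", -0.5), ("noise_sd", -2.0),
])
def test_invalid_spec_error_names_the_field(field, value):
    spec = dataclasses.replace(small_spec(), **{field: value})
    with pytest.raises(ValueError, match=field):
        generate_patient(spec)


def test_class_separability_monotone_in_eeg_effect():
    """Band-power AUC (preictal vs interictal) grows with eeg_effect.

    The oracle measures power in the upper half of the preictal band
    (above the episode-baseline band) so the class effect is isolated.
    """
    aucs = []
    for effect in (0.0, 1.0, 3.0):
        rec = generate_patient(small_spec(eeg_effect=effect,
                                          episode_shift=0.0))[0]
        vals, labels = bandpower_per_window(rec, 0.105, 0.12)
        aucs.append(roc_auc_score(labels, vals))
    assert aucs[0] < 0.65           # no effect: near-chance
    assert aucs[2] > aucs[0] + 0.2  # strong effect: clearly separable
    assert aucs[1] <= aucs[2] + 0.05  # non-decreasing within tolerance


def test_ecg_rate_increases_in_preictal():
    rec = generate_patient(small_spec(ecg_effect=2.0, noise_sd=0.5))[0]
    n_state = rec.n_samples // 2
    def beat_count(x):
        peaks, _ = sps.find_peaks(x, height=0.5, distance=int(0.2 * rec.fs))
        return len(peaks)
    assert beat_count(rec.ecg[n_state:]) > 1.3 * beat_count(rec.ecg[:n_state])


def test_episode_shift_detectable_from_interictal_bandpower():
    """A threshold on band power separates episodes when shift > 0 only.

    Interictal-only windows, measured in the upper half of the
    episode-baseline band (clear of the random episode-signature band).
    """
    for shift, expect_separable in ((2.0, True), (0.0, False)):
        recs = generate_patient(small_spec(episode_shift=shift, eeg_effect=0.0))
        vals, eps = [], []
        for rec in recs[:2]:
            v, labels = bandpower_per_window(rec, 0.09, 0.10)
            vals.extend(v[labels == 0])
            eps.extend([rec.episode_id] * int((labels == 0).sum()))
        auc = roc_auc_score(np.array(eps) > 0, vals)
        auc = max(auc, 1 - auc)
        if expect_separable:
            assert auc > 0.65
        else:
            assert auc < 0.65
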