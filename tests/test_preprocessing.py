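"""Filtering, normalization, segmentation and CWT correctness."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from hypothesis.extra import numpy as hnp

from seizefuse.preprocessing import (avgpool_time, cwt_scalogram,
                                     design_filters, filter_signal,
                                     mexican_hat, minmax_normalize,
                                     segment_windows)
from seizefuse.recording import Recording, INTERICTAL, PREICTAL


# -- filtering ----------------------------------------------------------------

def test_filter_removes_dc():
    fs = 512.0
    x = np.full(int(8 * fs), 3.7)
    y = filter_signal(x, fs)
    core = y[int(fs):-int(fs)]  # trim filter transients
    assert np.mean(core ** 2) < 1e-4 * np.mean(x ** 2)


def _gain_at(fs, hz):
    """Amplitude response of the full zero-phase cascade at one frequency."""
    from scipy import signal as sps
    sos_bp, sos_bs = design_filters(fs)
    _, h_bp = sps.sosfreqz(sos_bp, worN=[hz], fs=fs)
    gain = np.abs(h_bp[0]) ** 2  # forward-backward pass squares the response
    if sos_bs is not None:
        _, h_bs = sps.sosfreqz(sos_bs, worN=[hz], fs=fs)
        gain *= np.abs(h_bs[0]) ** 2
    return float(gain)


def test_filter_attenuates_mains_by_20db():
    assert _gain_at(512.0, 50.0) < 10 ** (-20 / 20)


def test_filter_preserves_10hz_within_5pct():
    assert abs(_gain_at(512.0, 10.0) - 1.0) < 0.05


def test_filter_rejects_low_sampling_rate():
    with pytest.raises(ValueError, match="fs"):
        filter_signal(np.zeros(100), fs=100.0, high=70.0)


def test_filter_preserves_length_and_supports_no_notch():
    x = np.random.default_rng(0).normal(size=(3, 640))
    y = filter_signal(x, fs=64.0, high=28.0, notch=None)
    assert y.shape == x.shape


# -- min-max normalization ----------------------------------------------------

def test_minmax_matches_definition():
    assert np.allclose(minmax_normalize(np.array([1.0, 2.0, 3.0])),
                       [0.0, 0.5, 1.0])


def test_minmax_constant_input_returns_zeros_with_warning():
    with pytest.warns(UserWarning, match="constant"):
        out = minmax_normalize(np.array([5.0, 5.0, 5.0]))
    assert np.array_equal(out, np.zeros(3))


@given(hnp.arrays(np.float64, st.integers(2, 50),
                  elements=st.floats(-1e6, 1e6, allow_nan=False)))
def test_minmax_bounds_and_order(x):
    out = minmax_normalize(x)
    assert out.min() >= 0.0 and out.max() <= 1.0
    if x.max() > x.min():
        assert np.isclose(out.min(), 0.0) and np.isclose(out.max(), 1.0)
        # order preservation
        i, j = np.argmin(x), np.argmax(x)
        assert out[i] <= out[j]


# -- segmentation -------------------------------------------------------------

def _recording(fs, intervals, n=None):
    n = n or max(e for _, e, _ in intervals)
    rng = np.random.default_rng(0)
    return Recording(rng.normal(size=(2, n)), rng.normal(size=n), fs, 3,
                     list(intervals))


def test_300s_interval_gives_exactly_300_windows():
    fs = 512.0
    rec = _recording(fs, [(0, int(300 * fs), PREICTAL)])
    eeg, ecg, y, d = segment_windows(rec, window_s=1.0, overlap=0.0)
    assert eeg.shape == (300, 2, 512)
    assert ecg.shape == (300, 512)
    assert np.all(y == 1) and np.all(d == 3)


def test_partial_trailing_window_is_dropped():
    fs = 64.0
    rec = _recording(fs, [(0, int(10.5 * fs), INTERICTAL)])
    eeg, *_ = segment_windows(rec, window_s=1.0)
    assert eeg.shape[0] == 10


def test_overlap_extension():
    fs = 64.0
    rec = _recording(fs, [(0, int(3 * fs), INTERICTAL)])
    eeg, *_ = segment_windows(rec, window_s=1.0, overlap=0.5)
    assert eeg.shape[0] == 5  # hop = half a window


def test_window_longer_than_intervals_warns_and_returns_empty():
    rec = _recording(64.0, [(0, 32, INTERICTAL)], n=64)
    with pytest.warns(UserWarning, match="window"):
        eeg, ecg, y, d = segment_windows(rec, window_s=1.0)
    assert eeg.shape[0] == 0


def test_total_count_matches_floor_formula():
    fs = 64.0
    intervals = [(0, 500, INTERICTAL), (512, 1500, PREICTAL),
                 (1504, 1600, INTERICTAL)]
    rec = _recording(fs, intervals)
    eeg, *_ = segment_windows(rec, window_s=1.0)
    expected = sum((e - s) // int(fs) for s, e, _ in intervals)
    assert eeg.shape[0] == expected


def test_windows_never_straddle_interval_boundaries():
    fs = 64.0
    rec = _recording(fs, [(0, 96, INTERICTAL), (96, 224, PREICTAL)])
    eeg, ecg, y, d = segment_windows(rec, window_s=1.0)
    # 96-sample interictal block yields 1 window, 128-sample preictal 2
    assert list(y) == [0, 1, 1]
    assert np.array_equal(ecg[1], rec.ecg[96:160])


# -- continuous wavelet transform ---------------------------------------------

def riemann_cwt(x, scales):
    """Independent oracle: direct Riemann sum of the CWT integral."""
    n = len(x)
    t = np.arange(n)
    out = np.empty((len(scales), n))
    for i, a in enumerate(scales):
        for b in range(n):
            out[i, b] = np.sum(x * mexican_hat((t - b) / a)) / np.sqrt(a)
    return out


def test_cwt_matches_riemann_sum_on_random_signals(rng):
    scales = np.arange(1, 33)
    for _ in range(5):
        x = rng.normal(size=512)
        got = cwt_scalogram(x, scales)
        want = riemann_cwt(x, scales)
        assert np.allclose(got, want, rtol=1e-3, atol=1e-6 * np.abs(want).max())


def test_cwt_impulse_matches_wavelet_shape():
    """A centered unit impulse reproduces the scaled wavelet row by row."""
    n = 129
    x = np.zeros(n)
    x[64] = 1.0
    out = cwt_scalogram(x, np.arange(1, 9))
    t = np.arange(n)
    for i, a in enumerate(range(1, 9)):
        expected = mexican_hat((t - 64) / a) / np.sqrt(a)
        assert np.allclose(out[i], expected, atol=1e-9)


def test_cwt_zero_signal_gives_zero_scalogram():
    assert np.all(cwt_scalogram(np.zeros(64)) == 0.0)


def test_cwt_is_linear(rng):
    x = rng.normal(size=64)
    assert np.allclose(cwt_scalogram(3.5 * x), 3.5 * cwt_scalogram(x))
    y = rng.normal(size=64)
    assert np.allclose(cwt_scalogram(x + y),
                       cwt_scalogram(x) + cwt_scalogram(y))


def test_cwt_agrees_with_pywavelets_convention():
    """Cross-check against an independent CWT implementation.

    pywt uses the same L2-normalized Mexican hat; its coefficients match
    ours up to its internal integration-grid accuracy.
    """
    import pywt

    rng = np.random.default_rng(5)
    x = rng.normal(size=256)
    # pywt approximates the wavelet by an integrated lookup table, which
    # is coarse at very small scales; compare on the mid/large scales
    scales = np.array([8, 16, 32])
    ours = cwt_scalogram(x, scales)
    theirs, _ = pywt.cwt(x, scales, "mexh", method="conv", precision=12)
    for i in range(len(scales)):
        assert np.corrcoef(ours[i], theirs[i])[0, 1] > 0.99
        slope = np.polyfit(ours[i], theirs[i], 1)[0]
        assert slope == pytest.approx(1.0, abs=0.02)


def test_avgpool_time():
    x = np.arange(12, dtype=float).reshape(1, 12)
    out = avgpool_time(x, 4)
    assert np.allclose(out, [[1.5, 5.5, 9.5]])
    assert avgpool_time(x, 1) is x
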