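"""Baseline removal, filtering, normalization, windowing, splitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import affectfuse as af
from affectfuse.preprocess import (
    BandSpec, bandpass_eeg, binarize_labels, lowpass_peripheral, make_split,
    preprocess_trial, remove_baseline, slide_windows, zscore,
)
from affectfuse.synthetic import TrialRecord


def _trial(signal, fs=128.0, n_eeg=None, ratings=(6.0, 4.0, 5.0, 5.0)):
    signal = np.asarray(signal, dtype=np.float64)
    n_eeg = signal.shape[0] if n_eeg is None else n_eeg
    names = tuple(f"ch{i}" for i in range(signal.shape[0]))
    return TrialRecord(1, 1, signal, fs, names, n_eeg, np.asarray(ratings),
                       ("valence", "arousal", "dominance", "liking"), 9)


# -- baseline removal ------------------------------------------------------

def test_remove_baseline_constant_segments():
    """Baseline epochs 1, 2, 3 (mean 2) subtracted from a constant-5 stimulus."""
    fs = 8
    seg = int(fs)
    base = np.concatenate([np.full(seg, 1.0), np.full(seg, 2.0), np.full(seg, 3.0)])
    stim = np.full(2 * seg, 5.0)
    tr = _trial(np.stack([np.concatenate([base, stim])]), fs=fs)
    out = remove_baseline(tr, n_segments=2)
    np.testing.assert_allclose(out.signal, 3.0)


def test_remove_baseline_self_reference_gives_zero():
    fs = 16
    one_sec = np.sin(np.arange(fs))
    sig = np.tile(one_sec, 6)[None, :]
    out = remove_baseline(_trial(sig, fs=fs), n_segments=3)
    np.testing.assert_allclose(out.signal, 0.0, atol=1e-12)


def test_remove_baseline_default_shape():
    tr = _trial(np.random.default_rng(0).standard_normal((40, 8064)))
    out = remove_baseline(tr)
    assert out.signal.shape == (40, 7680)  # 60 segments x 1 s x 128 Hz


def test_remove_baseline_too_short_errors():
    with pytest.raises(ValueError, match="need"):
        remove_baseline(_trial(np.zeros((2, 100))))


# -- filters ---------------------------------------------------------------

def _rms(x):
    return np.sqrt(np.mean(np.square(x)))


def _tone(freq, fs=128.0, seconds=60.0):
    t = np.arange(int(fs * seconds)) / fs
    return np.sin(2 * np.pi * freq * t)[None, :]


THETA = BandSpec("theta", 4, 8)


def test_bandpass_passband_and_stopband():
    inside = _tone(6.0)
    outside = _tone(50.0)
    assert _rms(bandpass_eeg(inside, THETA, 128)) >= 0.9 * _rms(inside)
    assert _rms(bandpass_eeg(outside, THETA, 128)) <= 0.01 * _rms(outside)
    dc = np.ones((1, 1280))
    assert _rms(bandpass_eeg(dc, THETA, 128)) < 1e-3


def test_bandpass_idempotent_in_passband():
    x = bandpass_eeg(_tone(6.0), THETA, 128)
    xx = bandpass_eeg(x, THETA, 128)
    assert abs(_rms(xx) - _rms(x)) / _rms(x) < 0.01


def test_bandpass_rejects_band_beyond_nyquist():
    with pytest.raises(ValueError, match="Nyquist"):
        bandpass_eeg(_tone(6.0), BandSpec("bad", 30, 70), 128)
    with pytest.raises(ValueError):
        BandSpec("inverted", 10, 4)


def test_lowpass_response():
    slow, fast = _tone(1.0), _tone(60.0)
    assert _rms(lowpass_peripheral(slow, 30, 128)) >= 0.9 * _rms(slow)
    assert _rms(lowpass_peripheral(fast, 30, 128)) <= 0.05 * _rms(fast)
    const = np.full((1, 1280), 2.5)
    np.testing.assert_allclose(lowpass_peripheral(const, 30, 128), 2.5, atol=1e-6)


# -- z-score ---------------------------------------------------------------

def test_zscore_hand_example():
    out = zscore(np.array([[1.0, 2.0, 3.0]]))
    np.testing.assert_allclose(out[0], [-1.22474487, 0.0, 1.22474487])


def test_zscore_moments_and_idempotence():
    x = np.random.default_rng(3).standard_normal((4, 1000))
    z = zscore(x)
    np.testing.assert_allclose(z.mean(axis=1), 0, atol=1e-9)
    np.testing.assert_allclose(z.std(axis=1), 1, atol=1e-9)
    np.testing.assert_allclose(zscore(z), z, atol=1e-9)


def test_zscore_constant_channel_names_culprit():
    x = np.vstack([np.random.default_rng(0).standard_normal(50), np.full(50, 3.0)])
    with pytest.raises(ValueError, match="GSR"):
        zscore(x, channel_names=["Fp1", "GSR"])


# -- labels ----------------------------------------------------------------

@pytest.mark.parametrize("rating,scale,expected", [
    (5, 9, 0), (6, 9, 1), (1, 9, 0), (9, 9, 1),
    (3, 5, 0), (4, 5, 1),
])
def test_binarize_midpoint_rule(rating, scale, expected):
    assert binarize_labels({"valence": rating}, scale)["valence"] == expected


def test_binarize_out_of_scale():
    with pytest.raises(ValueError, match="outside"):
        binarize_labels({"valence": 10}, 9)


# -- windows ---------------------------------------------------------------

def test_window_counts():
    fs = 128
    tr = _trial(np.random.default_rng(1).standard_normal((2, 60 * fs)))
    assert len(slide_windows(tr)) == 58  # floor((7680-384)/128)+1
    assert len(slide_windows(tr, window_seconds=60, step_seconds=60)) == 1
    assert len(slide_windows(tr, window_seconds=3, step_seconds=3)) == 20


def test_windows_carry_provenance_and_labels():
    tr = _trial(np.random.default_rng(1).standard_normal((3, 128 * 10)), n_eeg=2)
    ws = slide_windows(tr)
    assert [w.window_index for w in ws] == list(range(len(ws)))
    assert ws[0].start_sample == 0 and ws[1].start_sample == 128
    assert all(w.labels == {"valence": 1, "arousal": 0} for w in ws)
    assert ws[0].eeg.shape == (2, 384) and ws[0].peripheral.shape == (1, 384)


def test_window_longer_than_trial_errors():
    tr = _trial(np.zeros((1, 100)))
    with pytest.raises(ValueError, match="longer"):
        slide_windows(tr, window_seconds=3)


# -- splits ----------------------------------------------------------------

@pytest.mark.parametrize("n_subj,n_test,expect_train", [(32, 4, 28), (23, 3, 20)])
def test_split_partition_sizes(n_subj, n_test, expect_train):
    trials = {s: list(range(1, 41)) for s in range(1, n_subj + 1)}
    plan = make_split(list(trials), trials, n_test, seed=0)
    assert len(plan.test_subjects) == n_test
    assert len(plan.train_subjects) == expect_train
    assert not set(plan.train_subjects) & set(plan.test_subjects)
    for s in plan.train_subjects:
        assert len(plan.val_trials[s]) == 8  # 20% of 40
        assert not set(plan.train_trials[s]) & set(plan.val_trials[s])


def test_split_deterministic_and_too_many_test_subjects():
    trials = {s: [1, 2, 3] for s in range(5)}
    a = make_split(list(trials), trials, 2, seed=7)
    b = make_split(list(trials), trials, 2, seed=7)
    assert a.test_subjects == b.test_subjects
    assert a.val_trials == b.val_trials
    with pytest.raises(ValueError):
        make_split(list(trials), trials, 5)


def test_no_leakage_across_partitions(tiny_corpus):
    subjects = sorted({t.subject_id for t in tiny_corpus})
    per = {s: sorted({t.trial_id for t in tiny_corpus if t.subject_id == s})
           for s in subjects}
    plan = make_split(subjects, per, 1, seed=0)
    seen = {}
    for tr in tiny_corpus:
        for w in slide_windows(tr):
            part = plan.partition_of(w.subject_id, w.trial_id)
            key = (w.subject_id, w.trial_id)
            assert seen.setdefault(key, part) == part
    test_subjects = {s for (s, _), p in seen.items() if p == "test"}
    trainval_subjects = {s for (s, _), p in seen.items() if p != "test"}
    assert not test_subjects & trainval_subjects


def test_split_yaml_round_trip(tmp_path):
    trials = {s: [1, 2, 3, 4, 5] for s in range(1, 6)}
    plan = make_split(list(trials), trials, 1, seed=3)
    plan.to_yaml(tmp_path / "split.yaml")
    back = af.SplitPlan.from_yaml(tmp_path / "split.yaml")
    assert back.train_subjects == plan.train_subjects
    assert back.val_trials == plan.val_trials


# -- pipeline-level properties --------------------------------------------

@settings(max_examples=10, deadline=None)
@given(offset=st.floats(-50, 50))
def test_baseline_and_zscore_absorb_channel_offsets(offset):
    rng = np.random.default_rng(42)
    sig = rng.standard_normal((2, 128 * 8))
    tr = _trial(sig)
    tr_off = _trial(sig + offset)
    a = zscore(remove_baseline(tr, n_segments=5).signal)
    b = zscore(remove_baseline(tr_off, n_segments=5).signal)
    np.testing.assert_allclose(a, b, atol=1e-6)


def test_preprocess_trial_end_to_end(tiny_corpus):
    ws = preprocess_trial(tiny_corpus[0])
    # 20 s stimulus -> 17 windows of 3 s at 1 s step
    assert len(ws) == 18
    full = np.hstack([ws[0].eeg] + [w.eeg[:, -128:] for w in ws[1:]])
    assert abs(full.mean()) < 0.1  # z-scored upstream
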