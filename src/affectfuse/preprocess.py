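"""Signal conditioning and leakage-safe dataset splitting.

The pipeline for each trial is: baseline removal (subtract the mean of the
three 1 s pre-stimulus segments from every 1 s stimulus segment), broad
band-pass of the EEG (0.5-40 Hz, 5th-order Butterworth), 30 Hz low-pass of
the peripheral channels, per-channel z-score, and 3 s / 1 s-step sliding
windows.  All filters are applied zero-phase (forward-backward) so filtering
never shifts samples relative to window boundaries.

Splitting is subject-independent and trial-wise: test subjects are held out
entirely, and within training subjects trials are partitioned 8:2 into
train/validation.  All windows of a trial inherit the trial's partition, so
no window of a trial can ever appear on both sides of a boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy import signal as sps

from .synthetic import TrialRecord

__all__ = [
    "BandSpec",
    "DEFAULT_BANDS",
    "SignalWindow",
    "SplitPlan",
    "bandpass_eeg",
    "binarize_labels",
    "lowpass_peripheral",
    "make_split",
    "preprocess_trial",
    "remove_baseline",
    "slide_windows",
    "zscore",
]


@dataclass(frozen=True)
class BandSpec:
    """A named EEG frequency band [low, high] in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0 < self.low < self.high):
            raise ValueError(f"band {self.name}: need 0 < low < high, got {self.low}, {self.high}")


DEFAULT_BANDS: tuple[BandSpec, ...] = (
    BandSpec("theta", 4.0, 8.0),
    BandSpec("alpha", 8.0, 13.0),
    BandSpec("beta", 13.0, 30.0),
    BandSpec("gamma", 30.0, 40.0),
)


@dataclass
class SignalWindow:
    """One 3 s slice of a trial, with provenance and binary labels."""

    subject_id: int
    trial_id: int
    window_index: int
    start_sample: int  # 0-based inclusive; window covers [start, start + n)
    eeg: np.ndarray  # channels x samples
    peripheral: np.ndarray  # channels x samples
    labels: dict[str, int]  # dimension -> 0/1
    sampling_rate: float
    eeg_channel_names: tuple[str, ...] = ()
    peripheral_channel_names: tuple[str, ...] = ()


def remove_baseline(
    trial: TrialRecord,
    baseline_seconds: float = 3.0,
    segment_seconds: float = 1.0,
    n_segments: int = 60,
) -> TrialRecord:
    """Subtract the averaged pre-stimulus baseline from every stimulus segment.

    The first ``baseline_seconds`` are cut into 1 s epochs whose per-channel,
    per-sample mean is the baseline reference; it is subtracted from each of
    the ``n_segments`` subsequent stimulus segments, which are then
    re-concatenated in chronological order.  Output length is
    ``n_segments * segment_seconds * rate`` samples.
    """
    fs = trial.sampling_rate
    seg = int(round(segment_seconds * fs))
    n_base = int(round(baseline_seconds / segment_seconds))
    needed = (n_base + n_segments) * seg
    if trial.signal.shape[1] < needed:
        raise ValueError(
            f"trial {trial.subject_id}/{trial.trial_id}: need {needed} samples "
            f"({n_base} baseline + {n_segments} stimulus segments of {seg}), "
            f"got {trial.signal.shape[1]}"
        )
    x = trial.signal.astype(np.float64)
    base = x[:, : n_base * seg].reshape(x.shape[0], n_base, seg)
    base_mean = base.mean(axis=1)  # channels x seg
    stim = x[:, n_base * seg: needed].reshape(x.shape[0], n_segments, seg)
    removed = stim - base_mean[:, None, :]
    out = removed.reshape(x.shape[0], n_segments * seg)
    return TrialRecord(
        subject_id=trial.subject_id,
        trial_id=trial.trial_id,
        signal=out,
        sampling_rate=fs,
        channel_names=trial.channel_names,
        n_eeg=trial.n_eeg,
        ratings=trial.ratings,
        rating_dims=trial.rating_dims,
        scale_max=trial.scale_max,
    )


def _check_band(low: float, high: float, fs: float) -> None:
    if high >= fs / 2:
        raise ValueError(f"band edge {high} Hz >= Nyquist ({fs / 2} Hz)")
    if low <= 0:
        raise ValueError(f"band edge {low} Hz must be > 0")


def bandpass_eeg(x: np.ndarray, band: BandSpec, fs: float, order: int = 5) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis."""
    _check_band(band.low, band.high, fs)
    sos = sps.butter(order, [band.low, band.high], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=np.float64), axis=-1)


def lowpass_peripheral(x: np.ndarray, cutoff: float = 30.0, fs: float = 128.0,
                       order: int = 5) -> np.ndarray:
    """Zero-phase Butterworth low-pass along the last axis (default 30 Hz)."""
    if cutoff >= fs / 2:
        raise ValueError(f"cutoff {cutoff} Hz >= Nyquist ({fs / 2} Hz)")
    sos = sps.butter(order, cutoff, btype="lowpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=np.float64), axis=-1)


def zscore(x: np.ndarray, channel_names: Sequence[str] | None = None) -> np.ndarray:
    """Per-channel standardization (x - mean) / sd with the population sd.

    A zero-variance channel is a sensor-failure signature and raises, naming
    the channel.
    """
    x = np.asarray(x, dtype=np.float64)
    mu = x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, keepdims=True)  # population (ddof=0) convention
    bad = np.nonzero(sd.ravel() == 0)[0]
    if bad.size:
        names = ([channel_names[i] for i in bad] if channel_names is not None
                 else [f"#{i}" for i in bad])
        raise ValueError(f"zero-variance channel(s): {names}; cannot z-score")
    return (x - mu) / sd


def binarize_labels(ratings: Mapping[str, float] | np.ndarray, scale_max: int,
                    rating_dims: Sequence[str] | None = None) -> dict[str, int]:
    """Midpoint binarization: high (1) iff rating > (scale_max + 1) / 2.

    On the 1-9 scale the threshold is 5 (a rating of exactly 5 is low); on the
    1-5 scale it is 3, by the same midpoint convention.
    """
    if not isinstance(ratings, Mapping):
        if rating_dims is None:
            raise ValueError("rating_dims required when ratings is an array")
        ratings = dict(zip(rating_dims, np.asarray(ratings).tolist()))
    mid = (scale_max + 1) / 2.0
    out = {}
    for dim, r in ratings.items():
        if not (1 <= r <= scale_max):
            raise ValueError(f"rating {r} for {dim} outside [1, {scale_max}]")
        out[dim] = int(r > mid)
    return out


def slide_windows(trial: TrialRecord, window_seconds: float = 3.0,
                  step_seconds: float = 1.0,
                  label_dims: Sequence[str] = ("valence", "arousal")) -> list[SignalWindow]:
    """Cut a trial into overlapping windows; each inherits the trial's labels.

    Window count is ``floor((T - W) / S) + 1``; windows never span trials.
    """
    fs = trial.sampling_rate
    w = int(round(window_seconds * fs))
    s = int(round(step_seconds * fs))
    n = trial.signal.shape[1]
    if w > n:
        raise ValueError(f"window of {w} samples longer than trial ({n} samples)")
    dims = [d for d in label_dims if d in trial.rating_dims]
    labels = binarize_labels(
        {d: float(trial.ratings[trial.rating_dims.index(d)]) for d in dims},
        trial.scale_max)
    out = []
    for k, start in enumerate(range(0, n - w + 1, s)):
        out.append(SignalWindow(
            subject_id=trial.subject_id,
            trial_id=trial.trial_id,
            window_index=k,
            start_sample=start,
            eeg=trial.signal[: trial.n_eeg, start: start + w],
            peripheral=trial.signal[trial.n_eeg:, start: start + w],
            labels=dict(labels),
            sampling_rate=fs,
            eeg_channel_names=trial.eeg_channel_names,
            peripheral_channel_names=trial.peripheral_channel_names,
        ))
    return out


@dataclass
class SplitPlan:
    """Subject-independent, trial-wise partition of a corpus."""

    train_subjects: tuple[int, ...]
    test_subjects: tuple[int, ...]
    train_trials: dict[int, tuple[int, ...]]  # subject -> trial ids
    val_trials: dict[int, tuple[int, ...]]

    def __post_init__(self) -> None:
        if set(self.train_subjects) & set(self.test_subjects):
            raise ValueError("train and test subject sets overlap")
        for s in self.train_subjects:
            tr, va = set(self.train_trials.get(s, ())), set(self.val_trials.get(s, ()))
            if tr & va:
                raise ValueError(f"subject {s}: train and val trials overlap: {tr & va}")

    def partition_of(self, subject_id: int, trial_id: int) -> str:
        if subject_id in self.test_subjects:
            return "test"
        if trial_id in self.val_trials.get(subject_id, ()):
            return "val"
        if trial_id in self.train_trials.get(subject_id, ()):
            return "train"
        raise KeyError(f"trial {subject_id}/{trial_id} not covered by the split plan")

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "train_subjects": list(self.train_subjects),
            "test_subjects": list(self.test_subjects),
            "train_trials": {int(s): list(t) for s, t in self.train_trials.items()},
            "val_trials": {int(s): list(t) for s, t in self.val_trials.items()},
        }
        Path(path).write_text(yaml.safe_dump(payload))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SplitPlan":
        d = yaml.safe_load(Path(path).read_text())
        return cls(
            train_subjects=tuple(d["train_subjects"]),
            test_subjects=tuple(d["test_subjects"]),
            train_trials={int(s): tuple(t) for s, t in d["train_trials"].items()},
            val_trials={int(s): tuple(t) for s, t in d["val_trials"].items()},
        )


def make_split(subjects: Sequence[int], trials_per_subject: Mapping[int, Sequence[int]],
               n_test_subjects: int, val_ratio: float = 0.2, seed: int = 0) -> SplitPlan:
    """Hold out ``n_test_subjects`` whole subjects; split the rest's trials 8:2.

    Deterministic under ``seed``.  With 32 subjects and 4 test subjects this
    yields the 28/4 partition; with 23 and 3, the 20/3 partition.
    """
    subjects = list(subjects)
    if n_test_subjects >= len(subjects):
        raise ValueError(
            f"requested {n_test_subjects} test subjects from only {len(subjects)}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x51D]))
    order = rng.permutation(len(subjects))
    test = tuple(sorted(subjects[i] for i in order[:n_test_subjects]))
    train = tuple(sorted(subjects[i] for i in order[n_test_subjects:]))
    train_trials: dict[int, tuple[int, ...]] = {}
    val_trials: dict[int, tuple[int, ...]] = {}
    for s in train:
        tids = list(trials_per_subject[s])
        perm = rng.permutation(len(tids))
        n_val = max(1, int(round(val_ratio * len(tids)))) if len(tids) > 1 else 0
        val_trials[s] = tuple(sorted(tids[i] for i in perm[:n_val]))
        train_trials[s] = tuple(sorted(tids[i] for i in perm[n_val:]))
    return SplitPlan(train_subjects=train, test_subjects=test,
                     train_trials=train_trials, val_trials=val_trials)


def preprocess_trial(
    trial: TrialRecord,
    bands_lowcut: float = 0.5,
    bands_highcut: float = 40.0,
    peripheral_cutoff: float = 30.0,
    baseline_seconds: float = 3.0,
    n_segments: int | None = None,
    window_seconds: float = 3.0,
    step_seconds: float = 1.0,
    label_dims: Sequence[str] = ("valence", "arousal"),
) -> list[SignalWindow]:
    """Full conditioning chain for one trial, ending in sliding windows."""
    fs = trial.sampling_rate
    if n_segments is None:
        n_segments = int(trial.signal.shape[1] / fs - baseline_seconds)
    t = remove_baseline(trial, baseline_seconds=baseline_seconds, n_segments=n_segments)
    sig = np.array(t.signal, dtype=np.float64)
    broad = BandSpec("broad", bands_lowcut, bands_highcut)
    sig[: t.n_eeg] = bandpass_eeg(sig[: t.n_eeg], broad, fs)
    sig[t.n_eeg:] = lowpass_peripheral(sig[t.n_eeg:], peripheral_cutoff, fs)
    sig = zscore(sig, t.channel_names)
    t.signal = sig
    return slide_windows(t, window_seconds, step_seconds, label_dims)
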