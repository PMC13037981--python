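"""Synthetic multichannel physiological corpora.

Generates trials with the shape and coarse statistical structure of the two
public affect corpora this package targets: a 3 s pre-stimulus baseline
followed by 60 s of stimulus signal, 32 (or 14) EEG channels plus peripheral
channels, sampled at 128 Hz, with ordinal self-report ratings per trial.

The emotional "signal" is planted where the downstream features look for it:

* EEG channels are sums of band-limited filtered noise (theta/alpha/beta/
  gamma) plus broadband noise.  High-arousal trials get their beta/gamma
  variance scaled by ``1 + effect_size``, so the band-power *composition*
  changes and the effect survives per-channel z-scoring.  Valence shifts
  frontal alpha asymmetry (left vs right frontal channels).
* zEMG/tEMG amplitude scales with arousal; the plethysmograph carries a
  cardiac-rate oscillation whose amplitude rises weakly with arousal.
* GSR and temperature are slow drifts plus noise with no label effect.
* A per-subject constant amplitude offset is added to every channel so that
  baseline removal and normalization have something to remove.

Ratings are drawn uniformly over the ordinal scale; all label effects are
driven by the midpoint-binarized rating, so label binarization downstream is
exercised on the same convention.  None of this is a forward model of real
electrophysiology -- it is a controllable test bed with the right shapes.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import h5py
import numpy as np
from scipy import signal as sps

from .montages import (
    DEAP32_EEG_CHANNELS,
    DEAP_PERIPHERAL_CHANNELS,
    DREAMER14_EEG_CHANNELS,
    DREAMER_PERIPHERAL_CHANNELS,
)

__all__ = [
    "SyntheticSpec",
    "TrialRecord",
    "dreamer_like_spec",
    "generate_corpus",
    "iter_corpus",
    "read_archive",
    "write_archive",
]

_BANDS = {"theta": (4.0, 8.0), "alpha": (8.0, 13.0), "beta": (13.0, 30.0), "gamma": (30.0, 40.0)}
# Resting band-variance fractions (share of EEG variance per band).
_BASE_BAND_WEIGHT = {"theta": 0.30, "alpha": 0.30, "beta": 0.25, "gamma": 0.15}
_BROADBAND_WEIGHT = 0.15
_EEG_SCALE_UV = 10.0  # overall EEG amplitude scale, microvolts

_LEFT_FRONTAL = {"Fp1", "AF3", "F3", "F7", "FC5", "FC1"}
_RIGHT_FRONTAL = {"Fp2", "AF4", "F4", "F8", "FC6", "FC2"}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a generated corpus.

    Defaults reproduce the 32-subject archive layout: 63 s (3 s baseline +
    60 s stimulus) at 128 Hz = 8064 samples over 40 channels, ratings on a
    1-9 scale.
    """

    n_subjects: int = 32
    n_trials_per_subject: int = 40
    sampling_rate: float = 128.0
    baseline_seconds: float = 3.0
    stimulus_seconds: float = 60.0
    eeg_channels: tuple[str, ...] = DEAP32_EEG_CHANNELS
    peripheral_channels: tuple[str, ...] = DEAP_PERIPHERAL_CHANNELS
    rating_dims: tuple[str, ...] = ("valence", "arousal", "dominance", "liking")
    scale_max: int = 9
    effect_size: float = 1.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0 or self.n_trials_per_subject <= 0:
            raise ValueError("n_subjects and n_trials_per_subject must be positive")
        if self.baseline_seconds <= 0 or self.stimulus_seconds <= 0 or self.sampling_rate <= 0:
            raise ValueError("durations and sampling rate must be positive")
        if not self.eeg_channels or not self.peripheral_channels:
            raise ValueError("channel lists must be non-empty")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")

    @property
    def n_samples(self) -> int:
        return int(round((self.baseline_seconds + self.stimulus_seconds) * self.sampling_rate))

    @property
    def channel_names(self) -> tuple[str, ...]:
        return tuple(self.eeg_channels) + tuple(self.peripheral_channels)


def dreamer_like_spec(**overrides) -> SyntheticSpec:
    """A spec shaped like the 23-subject wearable corpus (14 EEG + 2 ECG, 1-5 scale)."""
    defaults = dict(
        n_subjects=23,
        n_trials_per_subject=18,
        eeg_channels=DREAMER14_EEG_CHANNELS,
        peripheral_channels=DREAMER_PERIPHERAL_CHANNELS,
        rating_dims=("valence", "arousal", "dominance"),
        scale_max=5,
    )
    defaults.update(overrides)
    return SyntheticSpec(**defaults)


@dataclass
class TrialRecord:
    """One stimulus presentation: raw signal plus self-report ratings."""

    subject_id: int
    trial_id: int
    signal: np.ndarray  # channels x samples, float32
    sampling_rate: float
    channel_names: tuple[str, ...]
    n_eeg: int
    ratings: np.ndarray  # one ordinal score per rating dimension
    rating_dims: tuple[str, ...]
    scale_max: int

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal)
        self.ratings = np.asarray(self.ratings, dtype=np.float32)
        if self.signal.shape[0] != len(self.channel_names):
            raise ValueError(
                f"signal has {self.signal.shape[0]} rows but "
                f"{len(self.channel_names)} channel names"
            )
        if np.any(self.ratings < 1) or np.any(self.ratings > self.scale_max):
            raise ValueError(f"ratings must lie in [1, {self.scale_max}]")

    @property
    def eeg(self) -> np.ndarray:
        return self.signal[: self.n_eeg]

    @property
    def peripheral(self) -> np.ndarray:
        return self.signal[self.n_eeg:]

    @property
    def eeg_channel_names(self) -> tuple[str, ...]:
        return self.channel_names[: self.n_eeg]

    @property
    def peripheral_channel_names(self) -> tuple[str, ...]:
        return self.channel_names[self.n_eeg:]


def _band_sos(low: float, high: float, fs: float):
    return sps.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")


def _band_noise(rng: np.random.Generator, sos, n: int) -> np.ndarray:
    """Unit-variance band-limited noise of length n."""
    pad = 256
    x = rng.standard_normal(n + 2 * pad)
    y = sps.sosfilt(sos, x)[pad:-pad]
    sd = y.std()
    return y / sd if sd > 0 else y


def _eeg_channel(
    rng: np.random.Generator,
    spec: SyntheticSpec,
    sos_cache: dict,
    name: str,
    arousal_high: bool,
    valence_high: bool,
    n_base: int,
    n_stim: int,
) -> np.ndarray:
    """One EEG channel: label-independent baseline, label-shaped stimulus."""
    segs = []
    for n, with_labels in ((n_base, False), (n_stim, True)):
        total = np.zeros(n)
        for band, (lo, hi) in _BANDS.items():
            w = _BASE_BAND_WEIGHT[band]
            if with_labels:
                if band in ("beta", "gamma") and arousal_high:
                    w *= 1.0 + spec.effect_size
                if band == "alpha" and name in (_LEFT_FRONTAL | _RIGHT_FRONTAL):
                    # high valence: alpha suppressed left / enhanced right
                    sign = -1.0 if name in _LEFT_FRONTAL else 1.0
                    shift = 0.25 * spec.effect_size * (1.0 if valence_high else -1.0)
                    w *= max(1.0 + sign * shift, 0.05)
            total += np.sqrt(w) * _band_noise(rng, sos_cache[band], n)
        total += np.sqrt(_BROADBAND_WEIGHT) * spec.noise_sd * rng.standard_normal(n)
        segs.append(total)
    return _EEG_SCALE_UV * np.concatenate(segs)


def _peripheral_channel(
    rng: np.random.Generator,
    spec: SyntheticSpec,
    name: str,
    arousal_high: bool,
    n_total: int,
    n_base: int,
) -> np.ndarray:
    fs = spec.sampling_rate
    t = np.arange(n_total) / fs
    effect = spec.effect_size if arousal_high else 0.0
    stim = np.zeros(n_total)
    stim[n_base:] = 1.0  # label effects only during stimulus
    noise = spec.noise_sd * rng.standard_normal(n_total)
    lname = name.lower()
    if "emg" in lname:
        amp = 2.0 * (1.0 + 0.6 * effect * stim)
        return amp * rng.standard_normal(n_total) + 0.2 * noise
    if "plethysmograph" in lname or "ecg" in lname:
        hr = rng.uniform(1.0, 1.3)  # beats per second
        amp = 3.0 * (1.0 + 0.3 * effect * stim)
        return amp * np.sin(2 * np.pi * hr * t + rng.uniform(0, 2 * np.pi)) + 0.3 * noise
    if "respiration" in lname:
        f = rng.uniform(0.2, 0.35)
        return 4.0 * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi)) + 0.3 * noise
    if "eog" in lname:
        slow = sps.sosfilt(sps.butter(2, 4.0, btype="lowpass", fs=fs, output="sos"),
                           rng.standard_normal(n_total))
        return 5.0 * slow + 0.3 * noise
    # GSR / temperature: slow drift + noise, no label effect
    drift = np.cumsum(rng.standard_normal(n_total)) / np.sqrt(n_total)
    return 2.0 * drift + 0.2 * noise


def iter_corpus(spec: SyntheticSpec) -> Iterator[TrialRecord]:
    """Stream the trials of a corpus without holding them all in memory."""
    root = np.random.SeedSequence([spec.seed, 0x5EED])
    subject_seeds = root.spawn(spec.n_subjects)
    n_base = int(round(spec.baseline_seconds * spec.sampling_rate))
    n_stim = int(round(spec.stimulus_seconds * spec.sampling_rate))
    sos_cache = {b: _band_sos(lo, hi, spec.sampling_rate) for b, (lo, hi) in _BANDS.items()}
    mid = (spec.scale_max + 1) / 2.0

    for s, sseed in enumerate(subject_seeds, start=1):
        srng = np.random.default_rng(sseed)
        # constant per-subject amplitude offset, one value per channel
        offsets = srng.normal(0.0, 5.0, size=len(spec.channel_names))
        for trial in range(1, spec.n_trials_per_subject + 1):
            ratings = srng.integers(1, spec.scale_max + 1, size=len(spec.rating_dims))
            by_dim = dict(zip(spec.rating_dims, ratings))
            arousal_high = by_dim.get("arousal", mid) > mid
            valence_high = by_dim.get("valence", mid) > mid
            rows = []
            for name in spec.eeg_channels:
                rows.append(_eeg_channel(srng, spec, sos_cache, name,
                                         arousal_high, valence_high, n_base, n_stim))
            for name in spec.peripheral_channels:
                rows.append(_peripheral_channel(srng, spec, name, arousal_high,
                                                n_base + n_stim, n_base))
            sig = np.asarray(rows) + offsets[:, None]
            yield TrialRecord(
                subject_id=s,
                trial_id=trial,
                signal=sig.astype(np.float32),
                sampling_rate=spec.sampling_rate,
                channel_names=spec.channel_names,
                n_eeg=len(spec.eeg_channels),
                ratings=ratings,
                rating_dims=spec.rating_dims,
                scale_max=spec.scale_max,
            )


def generate_corpus(spec: SyntheticSpec) -> list[TrialRecord]:
    """Generate all trials of a corpus (see :func:`iter_corpus` to stream)."""
    return list(iter_corpus(spec))


def write_archive(trials: Iterable[TrialRecord], path: str | Path) -> Path:
    """Write trials to an HDF5 archive plus a CSV manifest alongside.

    Layout: ``/subjects/s<id>/trials/t<id>`` groups with ``signal`` and
    ``ratings`` datasets and ``sampling_rate``/``channel_names``/``scale_max``
    attributes.
    """
    path = Path(path)
    manifest_rows = []
    n_written = 0
    with h5py.File(path, "w") as f:
        subjects = f.create_group("subjects")
        for tr in trials:
            g = subjects.require_group(f"s{tr.subject_id:02d}").require_group(
                "trials").create_group(f"t{tr.trial_id:03d}")
            g.create_dataset("signal", data=tr.signal.astype(np.float32))
            g.create_dataset("ratings", data=np.asarray(tr.ratings, dtype=np.float32))
            g.attrs["subject_id"] = tr.subject_id
            g.attrs["trial_id"] = tr.trial_id
            g.attrs["sampling_rate"] = tr.sampling_rate
            g.attrs["channel_names"] = list(tr.channel_names)
            g.attrs["rating_dims"] = list(tr.rating_dims)
            g.attrs["n_eeg"] = tr.n_eeg
            g.attrs["scale_max"] = tr.scale_max
            manifest_rows.append(
                (tr.subject_id, tr.trial_id, tr.signal.shape[0], tr.signal.shape[1]))
            n_written += 1
    if n_written == 0:
        path.unlink(missing_ok=True)
        raise ValueError("cannot write an empty archive")
    manifest = path.with_suffix(".manifest.csv")
    with open(manifest, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["subject_id", "trial_id", "n_channels", "n_samples"])
        w.writerows(manifest_rows)
    return path


def read_archive(path: str | Path) -> list[TrialRecord]:
    """Read an archive back into TrialRecords (inverse of :func:`write_archive`)."""
    out: list[TrialRecord] = []
    with h5py.File(path, "r") as f:
        if "subjects" not in f:
            raise ValueError(f"{path}: not a trial archive (missing /subjects group)")
        for sname in sorted(f["subjects"]):
            sg = f["subjects"][sname]
            if "trials" not in sg:
                raise ValueError(f"{path}: subject {sname} missing 'trials' group")
            for tname in sorted(sg["trials"]):
                g = sg["trials"][tname]
                for req in ("signal", "ratings"):
                    if req not in g:
                        raise ValueError(
                            f"{path}: trial {sname}/{tname} missing dataset '{req}'")
                for req in ("sampling_rate", "channel_names", "n_eeg", "scale_max"):
                    if req not in g.attrs:
                        raise ValueError(
                            f"{path}: trial {sname}/{tname} missing attribute '{req}'")
                names = tuple(str(c) for c in g.attrs["channel_names"])
                out.append(TrialRecord(
                    subject_id=int(g.attrs["subject_id"]),
                    trial_id=int(g.attrs["trial_id"]),
                    signal=g["signal"][()],
                    sampling_rate=float(g.attrs["sampling_rate"]),
                    channel_names=names,
                    n_eeg=int(g.attrs["n_eeg"]),
                    ratings=g["ratings"][()],
                    rating_dims=tuple(str(d) for d in g.attrs["rating_dims"]),
                    scale_max=int(g.attrs["scale_max"]),
                ))
    return out
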