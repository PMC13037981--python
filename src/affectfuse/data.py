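"""Window-level feature datasets and sequence batching.

``build_feature_dataset`` runs the conditioning chain on each trial (baseline
removal, broad EEG band-pass, peripheral low-pass, z-score), slides 3 s / 1 s
windows, and computes per window: channel-level DE values per band (the 9x9
grid placement happens inside the network via a fixed scatter matrix), the
five peripheral statistics per channel, and a time-pooled copy of the
peripheral samples for the LSTM branch.  Band filtering runs once per trial
per band, with window variances sliced from the filtered trace.

Sequences for the temporal model are runs of ``seq_len`` consecutive windows
of one trial (stride ``seq_stride``); a sequence never crosses a trial
boundary, so split hygiene at the trial level carries over to sequences.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np

from .features import ElectrodeGridMap, peripheral_stats_block, trial_band_power_windows
from .preprocess import DEFAULT_BANDS, BandSpec, SplitPlan, preprocess_trial
from .synthetic import TrialRecord

__all__ = ["FeatureDataset", "SequenceIndex", "build_feature_dataset", "scatter_matrix"]


def scatter_matrix(gridmap: ElectrodeGridMap, channels: Sequence[str]) -> np.ndarray:
    """(n_channels, rows*cols) 0/1 matrix placing channel i at its grid cell."""
    S = np.zeros((len(channels), gridmap.grid_rows * gridmap.grid_cols))
    for i, ch in enumerate(channels):
        r, c = gridmap.cell(ch)
        S[i, r * gridmap.grid_cols + c] = 1.0
    return S


@dataclass
class FeatureDataset:
    """Per-window features for a whole corpus, flat arrays with provenance."""

    de: np.ndarray          # (n_windows, n_eeg, n_bands)
    per_stats: np.ndarray   # (n_windows, l, 5)
    per_pooled: np.ndarray  # (n_windows, l, pooled_steps)
    labels: np.ndarray      # (n_windows, n_label_dims) 0/1
    subject_ids: np.ndarray
    trial_ids: np.ndarray
    window_index: np.ndarray
    label_dims: tuple[str, ...]
    band_names: tuple[str, ...]
    eeg_channel_names: tuple[str, ...]
    peripheral_channel_names: tuple[str, ...]
    sampling_rate: float

    def __len__(self) -> int:
        return self.de.shape[0]

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        with h5py.File(path, "w") as f:
            g = f.create_group("windows")
            for name in ("de", "per_stats", "per_pooled", "labels",
                         "subject_ids", "trial_ids", "window_index"):
                g.create_dataset(name, data=getattr(self, name))
            g.attrs["label_dims"] = list(self.label_dims)
            g.attrs["band_names"] = list(self.band_names)
            g.attrs["eeg_channel_names"] = list(self.eeg_channel_names)
            g.attrs["peripheral_channel_names"] = list(self.peripheral_channel_names)
            g.attrs["sampling_rate"] = self.sampling_rate
        return path

    @classmethod
    def load(cls, path: str | Path) -> "FeatureDataset":
        with h5py.File(path, "r") as f:
            g = f["windows"]
            return cls(
                de=g["de"][()], per_stats=g["per_stats"][()],
                per_pooled=g["per_pooled"][()], labels=g["labels"][()],
                subject_ids=g["subject_ids"][()], trial_ids=g["trial_ids"][()],
                window_index=g["window_index"][()],
                label_dims=tuple(str(x) for x in g.attrs["label_dims"]),
                band_names=tuple(str(x) for x in g.attrs["band_names"]),
                eeg_channel_names=tuple(str(x) for x in g.attrs["eeg_channel_names"]),
                peripheral_channel_names=tuple(
                    str(x) for x in g.attrs["peripheral_channel_names"]),
                sampling_rate=float(g.attrs["sampling_rate"]),
            )


def _pool_time(x: np.ndarray, steps: int) -> np.ndarray:
    """Average-pool the last axis down to ``steps`` blocks."""
    n = x.shape[-1]
    block = n // steps
    return x[..., : block * steps].reshape(*x.shape[:-1], steps, block).mean(axis=-1)


def build_feature_dataset(
    trials: Sequence[TrialRecord],
    bands: Sequence[BandSpec] = DEFAULT_BANDS,
    label_dims: Sequence[str] = ("valence", "arousal"),
    window_seconds: float = 3.0,
    step_seconds: float = 1.0,
    pooled_steps: int = 16,
) -> FeatureDataset:
    """Preprocess and featurize every trial of a corpus."""
    de_all, stats_all, pooled_all = [], [], []
    labels_all, subj_all, trial_all, widx_all = [], [], [], []
    band_names = tuple(b.name for b in bands)
    first = trials[0]
    dims = tuple(d for d in label_dims if d in first.rating_dims)
    for tr in trials:
        windows = preprocess_trial(tr, window_seconds=window_seconds,
                                   step_seconds=step_seconds, label_dims=dims)
        if not windows:
            continue
        fs = windows[0].sampling_rate
        n_w = windows[0].eeg.shape[1]
        starts = [w.start_sample for w in windows]
        # reconstruct the preprocessed trial-level EEG from the window slices
        trial_len = starts[-1] + n_w
        eeg = np.empty((tr.n_eeg, trial_len))
        for w in windows:
            eeg[:, w.start_sample: w.start_sample + n_w] = w.eeg
        var = trial_band_power_windows(eeg, fs, bands, starts, n_w)
        de_all.append(0.5 * np.log(2.0 * np.pi * np.e * var))
        for w in windows:
            stats_all.append(peripheral_stats_block(w.peripheral))
            pooled_all.append(_pool_time(w.peripheral, pooled_steps))
            labels_all.append([w.labels[d] for d in dims])
            subj_all.append(w.subject_id)
            trial_all.append(w.trial_id)
            widx_all.append(w.window_index)
    return FeatureDataset(
        de=np.concatenate(de_all, axis=0),
        per_stats=np.asarray(stats_all),
        per_pooled=np.asarray(pooled_all),
        labels=np.asarray(labels_all, dtype=np.int64),
        subject_ids=np.asarray(subj_all),
        trial_ids=np.asarray(trial_all),
        window_index=np.asarray(widx_all),
        label_dims=dims,
        band_names=band_names,
        eeg_channel_names=first.eeg_channel_names,
        peripheral_channel_names=first.peripheral_channel_names,
        sampling_rate=first.sampling_rate,
    )


@dataclass
class SequenceIndex:
    """Sequences of consecutive windows within trials, as row-index arrays."""

    rows: np.ndarray  # (n_sequences, seq_len) indices into a FeatureDataset
    subject_ids: np.ndarray  # (n_sequences,)
    trial_ids: np.ndarray

    def __len__(self) -> int:
        return self.rows.shape[0]

    @classmethod
    def build(cls, ds: FeatureDataset, seq_len: int, stride: int = 1) -> "SequenceIndex":
        rows, subs, tris = [], [], []
        keys = np.stack([ds.subject_ids, ds.trial_ids], axis=1)
        _, starts = np.unique(keys, axis=0, return_index=True)
        bounds = sorted(starts.tolist()) + [len(ds)]
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            n = hi - lo
            for s in range(0, n - seq_len + 1, stride):
                rows.append(np.arange(lo + s, lo + s + seq_len))
                subs.append(ds.subject_ids[lo])
                tris.append(ds.trial_ids[lo])
        if not rows:
            raise ValueError(f"no trial has {seq_len} consecutive windows")
        return cls(rows=np.asarray(rows), subject_ids=np.asarray(subs),
                   trial_ids=np.asarray(tris))

    def select(self, ds: FeatureDataset, split: SplitPlan,
               partition: str) -> "SequenceIndex":
        keep = np.array([
            split.partition_of(int(s), int(t)) == partition
            for s, t in zip(self.subject_ids, self.trial_ids)])
        if not keep.any():
            raise ValueError(f"no sequences fall in partition {partition!r}")
        return SequenceIndex(rows=self.rows[keep], subject_ids=self.subject_ids[keep],
                             trial_ids=self.trial_ids[keep])

    def batch(self, ds: FeatureDataset, idx: np.ndarray) -> dict:
        """Assemble batch arrays for sequence indices ``idx``."""
        r = self.rows[idx]  # (B, T)
        return {
            "de": ds.de[r],                    # (B, T, C, nb)
            "per_pooled": ds.per_pooled[r],    # (B, T, l, Tp)
            "per_stats": ds.per_stats[r],      # (B, T, l, 5)
            "labels": ds.labels[r[:, -1]],     # (B, n_dims) — trial-constant
            "subject_ids": self.subject_ids[idx],
            "trial_ids": self.trial_ids[idx],
        }
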