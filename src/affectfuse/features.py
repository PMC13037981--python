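"""Differential-entropy spatial feature volumes and peripheral statistics.

For a band-filtered EEG segment treated as Gaussian, the differential entropy
-integral f log f reduces to the closed form ``0.5 * ln(2*pi*e*sigma^2)``
(natural log, so the unit is nats).  Per 3 s window we compute one DE value
per channel per band, place it at the channel's cell of the 9x9 scalp grid
(unmapped cells zero), and stack the four band slices into a 9x9x4 volume.

Peripheral channels get five time-domain statistics per window: mean, sample
standard deviation (N-1), peak (max), skewness (population moments) and
excess kurtosis (the value is 0 for a normal distribution).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import montages
from .preprocess import DEFAULT_BANDS, BandSpec, SignalWindow, bandpass_eeg

__all__ = [
    "DEFeatureVolume",
    "ElectrodeGridMap",
    "de_volume",
    "default_gridmap",
    "differential_entropy",
    "featurize_window",
    "peripheral_stats",
    "trial_band_power_windows",
]

PERIPHERAL_STAT_NAMES = ("mean", "sd", "peak", "skewness", "kurtosis")


@dataclass(frozen=True)
class ElectrodeGridMap:
    """Injective channel -> (row, col) mapping onto the 9x9 scalp plane."""

    mapping: dict[str, tuple[int, int]]
    grid_rows: int = montages.GRID_ROWS
    grid_cols: int = montages.GRID_COLS

    def __post_init__(self) -> None:
        cells = list(self.mapping.values())
        if len(set(cells)) != len(cells):
            raise ValueError("grid mapping is not injective")
        for name, (r, c) in self.mapping.items():
            if not (0 <= r < self.grid_rows and 0 <= c < self.grid_cols):
                raise ValueError(f"{name}: cell {(r, c)} outside {self.grid_rows}x{self.grid_cols}")

    def __len__(self) -> int:
        return len(self.mapping)

    def __contains__(self, channel: str) -> bool:
        return channel in self.mapping

    def cell(self, channel: str) -> tuple[int, int]:
        try:
            return self.mapping[channel]
        except KeyError:
            raise KeyError(f"channel {channel!r} not in grid map") from None

    def scatter(self, values: Sequence[float], channels: Sequence[str]) -> np.ndarray:
        """Place per-channel values on the grid; unmapped cells are 0."""
        grid = np.zeros((self.grid_rows, self.grid_cols))
        for v, ch in zip(values, channels):
            r, c = self.cell(ch)
            grid[r, c] = v
        return grid

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(
            {ch: [int(r), int(c)] for ch, (r, c) in self.mapping.items()}))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ElectrodeGridMap":
        d = yaml.safe_load(Path(path).read_text())
        return cls(mapping={ch: (int(rc[0]), int(rc[1])) for ch, rc in d.items()})


def default_gridmap(montage: str) -> ElectrodeGridMap:
    """The shipped grid map for a named montage ('deap32' or 'dreamer14')."""
    try:
        channels = montages.MONTAGES[montage]
    except KeyError:
        raise ValueError(
            f"unknown montage {montage!r}; available: {sorted(montages.MONTAGES)}") from None
    return ElectrodeGridMap(mapping={ch: montages.grid_position(ch) for ch in channels})


@dataclass
class DEFeatureVolume:
    """9x9xB stack of per-band DE maps."""

    values: np.ndarray  # rows x cols x bands
    band_order: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3 or self.values.shape[2] != len(self.band_order):
            raise ValueError(f"volume shape {self.values.shape} inconsistent "
                             f"with {len(self.band_order)} bands")


def differential_entropy(samples: np.ndarray) -> float:
    """Gaussian differential entropy 0.5*ln(2*pi*e*var) of a sample, in nats.

    The variance is the population variance of the (band-filtered) samples:
    the closed form parameterizes the Gaussian by its variance, not by an
    unbiased estimator of it.
    """
    x = np.asarray(samples, dtype=np.float64).ravel()
    if x.size < 2:
        raise ValueError("differential entropy needs at least 2 samples")
    var = x.var()
    if var == 0:
        raise ValueError("zero-variance input: differential entropy is -inf")
    return float(0.5 * np.log(2.0 * np.pi * np.e * var))


def _de_from_var(var: np.ndarray) -> np.ndarray:
    return 0.5 * np.log(2.0 * np.pi * np.e * var)


def de_volume(
    eeg: np.ndarray,
    channel_names: Sequence[str],
    gridmap: ElectrodeGridMap,
    bands: Sequence[BandSpec] = DEFAULT_BANDS,
    fs: float = 128.0,
) -> DEFeatureVolume:
    """Band-filter each channel of a window, compute DE, scatter on the grid."""
    unknown = [c for c in channel_names if c not in gridmap]
    if unknown:
        raise KeyError(f"channels not in grid map: {unknown}")
    vol = np.zeros((gridmap.grid_rows, gridmap.grid_cols, len(bands)))
    for b, band in enumerate(bands):
        filt = bandpass_eeg(eeg, band, fs)
        des = [differential_entropy(filt[i]) for i in range(filt.shape[0])]
        vol[:, :, b] = gridmap.scatter(des, channel_names)
    return DEFeatureVolume(values=vol, band_order=tuple(b.name for b in bands))


def peripheral_stats(samples: np.ndarray) -> np.ndarray:
    """(mean, sample SD, peak, skewness, excess kurtosis) of one window channel."""
    x = np.asarray(samples, dtype=np.float64).ravel()
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    mu = x.mean()
    sd_pop = x.std()
    if sd_pop == 0:
        raise ValueError("zero standard deviation: skewness/kurtosis undefined")
    sd = x.std(ddof=1)
    z = (x - mu) / sd_pop
    skew = float((z ** 3).mean())
    kurt = float((z ** 4).mean() - 3.0)
    return np.array([mu, sd, x.max(), skew, kurt])


def peripheral_stats_block(peripheral: np.ndarray) -> np.ndarray:
    """Stack :func:`peripheral_stats` over channels into an l x 5 block."""
    return np.stack([peripheral_stats(row) for row in np.asarray(peripheral)])


def featurize_window(
    window: SignalWindow,
    gridmap: ElectrodeGridMap,
    bands: Sequence[BandSpec] = DEFAULT_BANDS,
) -> tuple[DEFeatureVolume, np.ndarray]:
    """DE volume plus l x 5 peripheral statistics for one window."""
    vol = de_volume(window.eeg, window.eeg_channel_names, gridmap, bands,
                    fs=window.sampling_rate)
    return vol, peripheral_stats_block(window.peripheral)


def trial_band_power_windows(
    eeg: np.ndarray,
    fs: float,
    bands: Sequence[BandSpec],
    starts: Sequence[int],
    n_window: int,
) -> np.ndarray:
    """Windowed per-band variances from one pass of filtering over a trial.

    Filtering the whole trial once per band and slicing windows out of the
    filtered signal avoids refiltering every (heavily overlapping) window and
    keeps filter transients at the trial edges instead of at every window
    edge.  Returns an array of shape (n_windows, n_channels, n_bands).
    """
    eeg = np.asarray(eeg, dtype=np.float64)
    out = np.empty((len(starts), eeg.shape[0], len(bands)))
    for b, band in enumerate(bands):
        filt = bandpass_eeg(eeg, band, fs)
        for w, s in enumerate(starts):
            seg = filt[:, s: s + n_window]
            out[w, :, b] = seg.var(axis=1)
    return out
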