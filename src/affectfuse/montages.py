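"""Electrode montages and the 9x9 scalp grid convention.

The spatial feature maps place each electrode's per-band differential-entropy
value at a fixed cell of a 9x9 matrix laid out like the 10-20 system viewed
from above: anterior rows at the top, the left hemisphere on the left, midline
in column 4.  Cells without an electrode stay zero.  The cell assignments are
a shipped, versioned convention (they follow the usual 10-20 planar projection
used for EEG image grids) rather than a pixel-exact copy of any figure.
"""

from __future__ import annotations

GRID_ROWS = 9
GRID_COLS = 9

# 32-channel montage in the channel order used by the DEAP recordings.
DEAP32_EEG_CHANNELS: tuple[str, ...] = (
    "Fp1", "AF3", "F3", "F7", "FC5", "FC1", "C3", "T7",
    "CP5", "CP1", "P3", "P7", "PO3", "O1", "Oz", "Pz",
    "Fp2", "AF4", "Fz", "F4", "F8", "FC6", "FC2", "Cz",
    "C4", "T8", "CP6", "CP2", "P4", "P8", "PO4", "O2",
)

# Peripheral channels recorded alongside (channels 33-40 of the archive).
DEAP_PERIPHERAL_CHANNELS: tuple[str, ...] = (
    "hEOG", "vEOG", "zEMG", "tEMG",
    "GSR", "Respiration belt", "Plethysmograph", "Temperature",
)

# 14-channel consumer-headset montage (Emotiv layout) plus two ECG leads.
DREAMER14_EEG_CHANNELS: tuple[str, ...] = (
    "AF3", "F7", "F3", "FC5", "T7", "P7", "O1",
    "O2", "P8", "T8", "FC6", "F4", "F8", "AF4",
)

DREAMER_PERIPHERAL_CHANNELS: tuple[str, ...] = ("ECG1", "ECG2")

# 10-20 positions on the 9x9 plane: (row, col), row 0 = front.
_TEN_TWENTY_GRID: dict[str, tuple[int, int]] = {
    "Fp1": (0, 3), "Fpz": (0, 4), "Fp2": (0, 5),
    "AF3": (1, 3), "AFz": (1, 4), "AF4": (1, 5),
    "F7": (2, 0), "F3": (2, 2), "Fz": (2, 4), "F4": (2, 6), "F8": (2, 8),
    "FC5": (3, 1), "FC1": (3, 3), "FCz": (3, 4), "FC2": (3, 5), "FC6": (3, 7),
    "T7": (4, 0), "C3": (4, 2), "Cz": (4, 4), "C4": (4, 6), "T8": (4, 8),
    "CP5": (5, 1), "CP1": (5, 3), "CPz": (5, 4), "CP2": (5, 5), "CP6": (5, 7),
    "P7": (6, 0), "P3": (6, 2), "Pz": (6, 4), "P4": (6, 6), "P8": (6, 8),
    "PO3": (7, 3), "POz": (7, 4), "PO4": (7, 5),
    "O1": (8, 3), "Oz": (8, 4), "O2": (8, 5),
}


def grid_position(channel: str) -> tuple[int, int]:
    """Return the (row, col) cell of an electrode on the 9x9 plane."""
    try:
        return _TEN_TWENTY_GRID[channel]
    except KeyError:
        raise KeyError(
            f"channel {channel!r} has no 9x9 grid position; known channels: "
            f"{sorted(_TEN_TWENTY_GRID)}"
        ) from None


MONTAGES: dict[str, tuple[str, ...]] = {
    "deap32": DEAP32_EEG_CHANNELS,
    "dreamer14": DREAMER14_EEG_CHANNELS,
}
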