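"""Channel attention, modality weighting, complementarity, and fusion.

The channel attention block scores every sensor channel from two pooled
summaries (per-channel max and mean over the feature axis) passed through a
shared bottleneck MLP; the two MLP outputs are summed and squashed by a
sigmoid, so every weight lies in (0, 1).  For EEG the 32 weights are
re-arranged onto the 9x9 scalp grid to scale the DE volume cell-wise.

Modality weights come from a single-layer perceptron per modality whose
scores are softmax-normalized, which enforces the sum-to-one constraint.
The complementarity coefficient between two modalities' feature sets is
C = I(Fa; Fb) / (H(Fa) * H(Fb)) with the plug-in estimators of
:mod:`affectfuse.mi` (a sqrt-denominator variant is available behind a
flag).  Fusion is mid-level: plain concatenation, EEG block first.

These are the numpy-level, explicitly-parameterized operations; the
trainable counterparts in :mod:`affectfuse.network` share the same math.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import mi
from .features import ElectrodeGridMap

__all__ = [
    "ChannelAttentionParams",
    "apply_channel_weights",
    "channel_pool",
    "channel_weights",
    "complementarity",
    "fuse",
    "modality_weights",
    "weights_to_grid",
]


@dataclass
class ChannelAttentionParams:
    """Weights of the shared bottleneck MLP for m channels, reduction r."""

    W1: np.ndarray  # (m/r, m)
    b1: np.ndarray  # (m/r,)
    W2: np.ndarray  # (m, m/r)
    b2: np.ndarray  # (m/r,) — added to the bottleneck output before W2
    r: int = 4

    def __post_init__(self) -> None:
        m_r, m = self.W1.shape
        if self.W2.shape != (m, m_r):
            raise ValueError(f"W2 shape {self.W2.shape} incompatible with W1 {self.W1.shape}")
        if m % self.r != 0 or m // self.r != m_r:
            raise ValueError(f"m={m} not divisible into m/r={m_r} with r={self.r}")

    @classmethod
    def zeros(cls, m: int, r: int = 4) -> "ChannelAttentionParams":
        return cls(W1=np.zeros((m // r, m)), b1=np.zeros(m // r),
                   W2=np.zeros((m, m // r)), b2=np.zeros(m // r), r=r)

    @classmethod
    def random(cls, m: int, r: int = 4, rng: np.random.Generator | None = None,
               scale: float = 0.5) -> "ChannelAttentionParams":
        rng = rng or np.random.default_rng(0)
        return cls(W1=scale * rng.standard_normal((m // r, m)),
                   b1=scale * rng.standard_normal(m // r),
                   W2=scale * rng.standard_normal((m, m // r)),
                   b2=scale * rng.standard_normal(m // r), r=r)


def channel_pool(sample: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel (max, mean) over the feature axis of an m x F sample."""
    x = np.asarray(sample, dtype=np.float64)
    if x.ndim != 2 or x.shape[1] == 0:
        raise ValueError(f"expected m x F sample with F >= 1, got shape {x.shape}")
    return x.max(axis=1), x.mean(axis=1)


def _bottleneck(v: np.ndarray, p: ChannelAttentionParams) -> np.ndarray:
    return p.W2 @ (np.maximum(p.W1 @ v + p.b1, 0.0) + p.b2)


def channel_weights(sample: np.ndarray, params: ChannelAttentionParams) -> np.ndarray:
    """Sigmoid channel scores from pooled max/mean through the shared MLP."""
    mx, avg = channel_pool(sample)
    if params.W1.shape[1] != mx.size:
        raise ValueError(
            f"params expect {params.W1.shape[1]} channels, sample has {mx.size}")
    logits = _bottleneck(mx, params) + _bottleneck(avg, params)
    with np.errstate(over="ignore"):  # saturated sigmoid is well-defined
        return 1.0 / (1.0 + np.exp(-logits))


def apply_channel_weights(sample: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Scale each channel (row) of a sample by its attention weight."""
    x = np.asarray(sample, dtype=np.float64)
    w = np.asarray(weights, dtype=np.float64).ravel()
    if x.shape[0] != w.size:
        raise ValueError(f"{w.size} weights for {x.shape[0]} channels")
    return w[:, None] * x


def weights_to_grid(weights: np.ndarray, channels: Sequence[str],
                    gridmap: ElectrodeGridMap) -> np.ndarray:
    """Re-arrange per-channel weights onto the 9x9 plane (unmapped cells 0)."""
    return gridmap.scatter(np.asarray(weights, dtype=np.float64).ravel(), channels)


def complementarity(Fa: np.ndarray, Fb: np.ndarray, n_bins: int = mi.DEFAULT_BINS,
                    sqrt_denominator: bool = False) -> float:
    """Mutual information between two feature sets over the product of entropies."""
    i_ab = mi.pairwise_feature_mi(Fa, Fb, n_bins)
    denom = mi.feature_entropy(Fa, n_bins) * mi.feature_entropy(Fb, n_bins)
    if sqrt_denominator:
        denom = float(np.sqrt(denom))
    if denom == 0:
        raise ValueError("zero feature entropy: complementarity undefined")
    return float(i_ab / denom)


def modality_weights(features_per_modality: Sequence[np.ndarray],
                     perceptron_params: Sequence[tuple[np.ndarray, float]]) -> np.ndarray:
    """Softmax-normalized single-layer-perceptron scores, one per modality."""
    if len(features_per_modality) == 0:
        raise ValueError("at least one modality required")
    if len(perceptron_params) != len(features_per_modality):
        raise ValueError("one (weight, bias) pair required per modality")
    scores = []
    for f, (w, b) in zip(features_per_modality, perceptron_params):
        f = np.asarray(f, dtype=np.float64).ravel()
        w = np.asarray(w, dtype=np.float64).ravel()
        if f.size != w.size:
            raise ValueError(f"perceptron weight dim {w.size} != feature dim {f.size}")
        scores.append(float(w @ f + b))
    s = np.asarray(scores)
    e = np.exp(s - s.max())
    return e / e.sum()


def fuse(eeg_features: np.ndarray, peripheral_features: np.ndarray) -> np.ndarray:
    """Mid-level fusion: concatenate along the feature axis, EEG block first."""
    a = np.asarray(eeg_features, dtype=np.float64).ravel()
    b = np.asarray(peripheral_features, dtype=np.float64).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both modality feature blocks must be non-empty")
    return np.concatenate([a, b])
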