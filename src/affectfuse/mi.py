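"""Plug-in mutual-information and entropy estimation on quantized features.

The complementarity coefficient and the mutual-information loss both need
MI/entropy estimates of continuous feature sets.  The canonical estimator
here is deliberately simple and deterministic: each feature dimension is
quantized into equal-frequency bins (16 by default), and MI/entropy are the
plug-in estimates on the resulting discrete codes, averaged over feature
dimensions (dimension i of one set is paired with dimension i of the other,
cycling the shorter set).  On already-discrete inputs with few distinct
values the quantization is exact, which is what the enumeration tests use.
All quantities are in nats.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "discrete_entropy",
    "discrete_mi",
    "feature_entropy",
    "feature_label_mi",
    "pairwise_feature_mi",
    "quantile_codes",
]

DEFAULT_BINS = 16


def quantile_codes(x: np.ndarray, n_bins: int = DEFAULT_BINS) -> np.ndarray:
    """Equal-frequency bin codes of a 1-D sample.

    Bin edges are interior quantiles; ties collapse duplicate edges, so a
    sample with k < n_bins distinct values gets (at most) k codes.  A sample
    with a single distinct value is degenerate and raises.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    if np.unique(x).size < 2:
        raise ValueError("degenerate feature: a single distinct value cannot be binned")
    qs = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    edges = np.unique(qs)
    return np.searchsorted(edges, x, side="left")


def discrete_entropy(codes: np.ndarray) -> float:
    """Plug-in Shannon entropy of discrete codes, in nats."""
    _, counts = np.unique(np.asarray(codes).ravel(), return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def discrete_mi(a: np.ndarray, b: np.ndarray) -> float:
    """Plug-in mutual information of two paired discrete code vectors, nats."""
    a = np.asarray(a).ravel()
    b = np.asarray(b).ravel()
    if a.shape != b.shape:
        raise ValueError(f"paired samples required, got {a.shape} vs {b.shape}")
    ai, a_inv = np.unique(a, return_inverse=True)
    bi, b_inv = np.unique(b, return_inverse=True)
    joint = np.zeros((ai.size, bi.size))
    np.add.at(joint, (a_inv, b_inv), 1.0)
    p = joint / joint.sum()
    pa = p.sum(axis=1, keepdims=True)
    pb = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float((p[nz] * np.log(p[nz] / (pa @ pb)[nz])).sum())


def _as_2d(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    return x[:, None] if x.ndim == 1 else x


def feature_entropy(features: np.ndarray, n_bins: int = DEFAULT_BINS) -> float:
    """Entropy of a feature set: per-dimension plug-in entropy, averaged."""
    f = _as_2d(features)
    return float(np.mean([discrete_entropy(quantile_codes(f[:, j], n_bins))
                          for j in range(f.shape[1])]))


def feature_label_mi(features: np.ndarray, labels: np.ndarray,
                     n_bins: int = DEFAULT_BINS) -> float:
    """MI between a feature set and discrete labels, averaged over dimensions."""
    f = _as_2d(features)
    y = np.asarray(labels).ravel()
    return float(np.mean([discrete_mi(quantile_codes(f[:, j], n_bins), y)
                          for j in range(f.shape[1])]))


def pairwise_feature_mi(a: np.ndarray, b: np.ndarray,
                        n_bins: int = DEFAULT_BINS) -> float:
    """MI between two feature sets, averaged over index-paired dimensions."""
    fa, fb = _as_2d(a), _as_2d(b)
    if fa.shape[0] != fb.shape[0]:
        raise ValueError("feature sets must have matched sample counts")
    d = max(fa.shape[1], fb.shape[1])
    vals = [discrete_mi(quantile_codes(fa[:, j % fa.shape[1]], n_bins),
                        quantile_codes(fb[:, j % fb.shape[1]], n_bins))
            for j in range(d)]
    return float(np.mean(vals))
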