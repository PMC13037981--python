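"""The CDOM network and its ablations.

Per 3 s window the model sees (i) a 9x9x4 differential-entropy volume built
from per-channel, per-band DE values, and (ii) a peripheral block of
per-channel LSTM features plus five time-domain statistics.  Channel
attention (when enabled) scores EEG electrodes from their band-DE profile
and peripheral sensors from their feature block, and the EEG scores are
re-arranged onto the scalp grid before the convolutional branch.  The
depthwise-separable CNN (2 depthwise 3x3 + 2 pointwise 1x1 layers, 64
channels, ReLU, dropout 0.2) extracts spatial features; modality weights
from a single-layer perceptron (softmax, so they sum to one) scale each
modality before mid-level concatenation.  The fused per-window vectors of a
trial form a short sequence fed to a 2-layer bidirectional ordered-neuron
LSTM (hidden 128 per direction, forget-gate bias 1, recurrent dropout 0.2),
whose outputs are projected to the 512-dimensional attention space; 8-head
scaled dot-product attention with the last-step output as the query,
dropout 0.1, a residual connection and layer normalization produce the
vector classified by per-dimension softmax heads.

Variants: DO (no channel attention, no multi-head attention: the last
recurrent state goes straight to the classifier), CDO (+channel attention),
DOM (+multi-head attention), CDOM (both).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from .autograd import Tensor, cat, no_grad, stack

__all__ = [
    "CdomNet",
    "DscConfig",
    "MhaConfig",
    "ModelConfig",
    "Module",
    "OnLstmConfig",
    "forward",
    "load_checkpoint",
    "save_checkpoint",
]

VARIANTS = ("DO", "CDO", "DOM", "CDOM")


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass
class DscConfig:
    depthwise_layers: int = 2
    pointwise_layers: int = 2
    kernel: int = 3
    channels: int = 64
    dropout: float = 0.2


@dataclass
class OnLstmConfig:
    hidden: int = 128
    layers: int = 2
    bidirectional: bool = True
    forget_bias_init: float = 1.0
    recurrent_dropout: float = 0.2
    chunk_factor: int = 8  # master-gate chunk size; hidden must be divisible


@dataclass
class MhaConfig:
    heads: int = 8
    head_dim: int = 64
    hidden: int = 512
    dropout: float = 0.1

    def __post_init__(self) -> None:
        if self.heads * self.head_dim != self.hidden:
            raise ValueError(
                f"heads x head_dim must equal hidden: {self.heads}x{self.head_dim}"
                f" != {self.hidden}")


@dataclass
class ModelConfig:
    """Architecture hyperparameters; defaults are the fixed reference values."""

    variant: str = "CDOM"
    dsc: DscConfig = field(default_factory=DscConfig)
    onlstm: OnLstmConfig = field(default_factory=OnLstmConfig)
    mha: MhaConfig = field(default_factory=MhaConfig)
    n_classes: int = 2
    label_dims: tuple[str, ...] = ("valence", "arousal")
    reduction_ratio: int = 4
    spatial_embed_dim: int = 128
    peripheral_lstm_hidden: int = 8
    peripheral_steps: int = 16
    seq_len: int = 6
    seq_stride: int = 3
    use_peripheral_lstm: bool = True
    use_peripheral_stats: bool = True
    standard_lstm: bool = False  # force master gates open (plain-LSTM fallback)

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")
        if not (self.use_peripheral_lstm or self.use_peripheral_stats):
            raise ValueError("peripheral branch needs LSTM features, statistics, or both")

    @property
    def use_channel_attention(self) -> bool:
        return self.variant in ("CDO", "CDOM")

    @property
    def use_mha(self) -> bool:
        return self.variant in ("DOM", "CDOM")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        for key, sub in (("dsc", DscConfig), ("onlstm", OnLstmConfig), ("mha", MhaConfig)):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        for key in ("label_dims",):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


# --------------------------------------------------------------------------
# module machinery
# --------------------------------------------------------------------------

class Module:
    """Base class: parameter discovery, train/eval mode, init RNG plumbing."""

    def __init__(self) -> None:
        self.training = True

    def modules(self) -> Iterator["Module"]:
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for k, v in self.__dict__.items():
            name = f"{prefix}{k}"
            if isinstance(v, Tensor) and v.requires_grad:
                yield name, v
            elif isinstance(v, Module):
                yield from v.named_parameters(f"{name}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{name}.{i}.")
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield f"{name}.{i}", item

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def train(self) -> "Module":
        for m in self.modules():
            m.training = True
        return self

    def eval(self) -> "Module":
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[-2], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def _dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or p <= 0:
        return x
    mask = (rng.random(x.shape) >= p) / (1.0 - p)
    return x * Tensor(mask)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.W = Tensor(_glorot(rng, (n_in, n_out)), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return self.gamma * (xc * (var + self.eps).pow(-0.5)) + self.beta


def _depthwise_conv2d(x: Tensor, W: Tensor, b: Tensor, k: int) -> Tensor:
    """Fused 'same' per-channel 2-D convolution (one autograd node).

    x: (B, C, H, W); W: (C, k, k); b: (C,).  Implemented as a single einsum
    over a sliding-window view; the input gradient is the correlation of the
    output gradient with the flipped kernel.
    """
    from numpy.lib.stride_tricks import sliding_window_view

    pad = k // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))  # (B, C, H, W, k, k)
    out = np.einsum("bchwij,cij->bchw", win, W.data, optimize=True)
    out += b.data[None, :, None, None]

    def backward(g):
        if W.requires_grad:
            W._accum(np.einsum("bchwij,bchw->cij", win, g, optimize=True))
        if b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gp = np.pad(g, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
            gwin = sliding_window_view(gp, (k, k), axis=(2, 3))
            flipped = W.data[:, ::-1, ::-1]
            x._accum(np.einsum("bchwij,cij->bchw", gwin, flipped, optimize=True))

    return Tensor._make(out, (x, W, b), backward)


class DepthwiseConv2d(Module):
    """3x3 per-channel convolution, stride 1, 'same' zero padding."""

    def __init__(self, channels: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        self.kernel = kernel
        limit = np.sqrt(6.0 / (kernel * kernel * 2))
        self.W = Tensor(rng.uniform(-limit, limit, size=(channels, kernel, kernel)),
                        requires_grad=True)
        self.b = Tensor(np.zeros(channels), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return _depthwise_conv2d(x, self.W, self.b, self.kernel)


class PointwiseConv2d(Module):
    """1x1 convolution: cross-channel mixing."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        self.W = Tensor(_glorot(rng, (c_in, c_out)), requires_grad=True)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        flat = x.transpose(0, 2, 3, 1).reshape(B * H * W, C)
        out = flat @ self.W + self.b
        return out.reshape(B, H, W, -1).transpose(0, 3, 1, 2)


class DepthwiseSeparableCnn(Module):
    """(depthwise 3x3 -> pointwise 1x1) x 2, ReLU + dropout after each layer."""

    def __init__(self, c_in: int, cfg: DscConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.dw1 = DepthwiseConv2d(c_in, cfg.kernel, rng)
        self.pw1 = PointwiseConv2d(c_in, cfg.channels, rng)
        self.dw2 = DepthwiseConv2d(cfg.channels, cfg.kernel, rng)
        self.pw2 = PointwiseConv2d(cfg.channels, cfg.channels, rng)

    def __call__(self, x: Tensor, rng: np.random.Generator) -> Tensor:
        p = self.cfg.dropout
        for layer in (self.dw1, self.pw1, self.dw2, self.pw2):
            x = layer(x).relu()
            if self.training and p > 0:
                # channelwise (spatial) dropout: drop whole feature maps
                mask = (rng.random((x.shape[0], x.shape[1], 1, 1)) >= p) / (1.0 - p)
                x = x * Tensor(mask)
        B = x.shape[0]
        return x.reshape(B, -1)


class OnLstmCell(Module):
    """Ordered-neuron LSTM cell with cumulative-softmax master gates.

    The master forget gate (a cumulative softmax over hidden chunks) and the
    master input gate (its mirror) impose an ordering on hidden units; with
    the masters forced fully open the cell is exactly a standard LSTM.
    """

    def __init__(self, n_in: int, hidden: int, chunk: int, forget_bias: float,
                 rng: np.random.Generator, master_open: bool = False):
        super().__init__()
        if hidden % chunk != 0:
            raise ValueError(f"hidden {hidden} not divisible by chunk factor {chunk}")
        self.hidden = hidden
        self.chunk = chunk
        self.n_master = hidden // chunk
        self.master_open = master_open
        n_gates = 4 * hidden + 2 * self.n_master
        self.W = Tensor(_glorot(rng, (n_in, n_gates)), requires_grad=True)
        self.U = Tensor(_glorot(rng, (hidden, n_gates)), requires_grad=True)
        bias = np.zeros(n_gates)
        bias[hidden: 2 * hidden] = forget_bias  # forget-gate bias init
        self.b = Tensor(bias, requires_grad=True)
        self._expand = Tensor(np.ones((1, chunk)))  # repeats master values per chunk

    def __call__(self, x: Tensor, h: Tensor, c: Tensor) -> tuple[Tensor, Tensor]:
        H, M = self.hidden, self.n_master
        pre = x @ self.W + h @ self.U + self.b
        i = pre[:, :H].sigmoid()
        f = pre[:, H: 2 * H].sigmoid()
        o = pre[:, 2 * H: 3 * H].sigmoid()
        g = pre[:, 3 * H: 4 * H].tanh()
        if self.master_open:
            c_new = f * c + i * g
        else:
            mf = pre[:, 4 * H: 4 * H + M].cumsoftmax(axis=-1)
            mi_ = 1.0 - pre[:, 4 * H + M:].cumsoftmax(axis=-1)
            B = x.shape[0]
            mf = (mf.reshape(B, M, 1) @ self._expand).reshape(B, H)
            mi_ = (mi_.reshape(B, M, 1) @ self._expand).reshape(B, H)
            omega = mf * mi_
            f_hat = f * omega + (mf - omega)
            i_hat = i * omega + (mi_ - omega)
            c_new = f_hat * c + i_hat * g
        h_new = o * c_new.tanh()
        return h_new, c_new


class OnLstm(Module):
    """Multi-layer (bi)directional ON-LSTM over (B, T, F) sequences."""

    def __init__(self, n_in: int, cfg: OnLstmConfig, rng: np.random.Generator,
                 master_open: bool = False):
        super().__init__()
        self.cfg = cfg
        self.cells: list[OnLstmCell] = []
        dirs = 2 if cfg.bidirectional else 1
        for layer in range(cfg.layers):
            size = n_in if layer == 0 else cfg.hidden * dirs
            for _ in range(dirs):
                self.cells.append(OnLstmCell(size, cfg.hidden, cfg.chunk_factor,
                                             cfg.forget_bias_init, rng, master_open))

    @property
    def out_dim(self) -> int:
        return self.cfg.hidden * (2 if self.cfg.bidirectional else 1)

    def __call__(self, x: Tensor, rng: np.random.Generator) -> tuple[Tensor, Tensor]:
        """Returns (all-step outputs (B, T, Z), last-step output (B, 1, Z))."""
        B, T = x.shape[0], x.shape[1]
        if T == 0:
            raise ValueError("empty sequence (T=0)")
        dirs = 2 if self.cfg.bidirectional else 1
        seq = x
        for layer in range(self.cfg.layers):
            outs_dir = []
            for d in range(dirs):
                cell = self.cells[layer * dirs + d]
                h = Tensor(np.zeros((B, self.cfg.hidden)))
                c = Tensor(np.zeros((B, self.cfg.hidden)))
                steps = range(T) if d == 0 else range(T - 1, -1, -1)
                outs: dict[int, Tensor] = {}
                for t in steps:
                    h, c = cell(seq[:, t, :], h, c)
                    outs[t] = h
                outs_dir.append(stack([outs[t] for t in range(T)], axis=1))
            seq = cat(outs_dir, axis=-1) if dirs == 2 else outs_dir[0]
            if layer < self.cfg.layers - 1:
                seq = _dropout(seq, self.cfg.recurrent_dropout, rng, self.training)
        return seq, seq[:, T - 1: T, :]


class PlainLstm(Module):
    """Single-layer unidirectional LSTM (peripheral feature extractor)."""

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.cell = OnLstmCell(n_in, hidden, hidden, 1.0, rng, master_open=True)
        self.hidden = hidden

    def __call__(self, x: Tensor) -> Tensor:
        B, T = x.shape[0], x.shape[1]
        h = Tensor(np.zeros((B, self.hidden)))
        c = Tensor(np.zeros((B, self.hidden)))
        for t in range(T):
            h, c = self.cell(x[:, t, :], h, c)
        return h


def single_head_attention(Q: Tensor, K: Tensor, V: Tensor) -> tuple[Tensor, Tensor]:
    """Scaled dot-product attention over the time axis.

    Q: (B, 1, d), K/V: (B, T, d).  Returns (context (B, 1, d), scores
    (B, 1, T)); score rows sum to 1.
    """
    if Q.shape[-1] != K.shape[-1] or K.shape[-1] != V.shape[-1]:
        raise ValueError(f"head dims differ: Q {Q.shape}, K {K.shape}, V {V.shape}")
    dk = Q.shape[-1]
    scores = ((Q @ K.swapaxes(-1, -2)) * (1.0 / np.sqrt(dk))).softmax(axis=-1)
    return scores @ V, scores


class MultiHeadAttention(Module):
    """8-head attention querying all-step outputs with the last-step output."""

    def __init__(self, cfg: MhaConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        Z, N = cfg.hidden, cfg.heads
        d = cfg.head_dim
        self.Wq = [Linear(Z, d, rng) for _ in range(N)]
        self.Wk = [Linear(Z, d, rng) for _ in range(N)]
        self.Wv = [Linear(Z, d, rng) for _ in range(N)]
        self.norm = LayerNorm(Z)

    def __call__(self, oall: Tensor, olast: Tensor,
                 rng: np.random.Generator) -> Tensor:
        Z = self.cfg.hidden
        if oall.shape[-1] != Z or Z % self.cfg.heads != 0:
            raise ValueError(
                f"feature dim {oall.shape[-1]} incompatible with hidden {Z} / "
                f"{self.cfg.heads} heads")
        contexts = []
        for wq, wk, wv in zip(self.Wq, self.Wk, self.Wv):
            ctx, _ = single_head_attention(wq(olast), wk(oall), wv(oall))
            contexts.append(ctx)
        multi = cat(contexts, axis=-1)  # (B, 1, Z)
        multi = _dropout(multi, self.cfg.dropout, rng, self.training)
        return self.norm(olast + multi).reshape(multi.shape[0], Z)


class ChannelAttention(Module):
    """Trainable dual-pooling channel attention (shared bottleneck MLP)."""

    def __init__(self, m: int, r: int, rng: np.random.Generator):
        super().__init__()
        r = _compatible_reduction(m, r)
        self.m, self.r = m, r
        self.W1 = Tensor(_glorot(rng, (m, m // r)), requires_grad=True)
        self.b1 = Tensor(np.zeros(m // r), requires_grad=True)
        self.W2 = Tensor(_glorot(rng, (m // r, m)), requires_grad=True)
        self.b2 = Tensor(np.zeros(m // r), requires_grad=True)

    def _mlp(self, v: Tensor) -> Tensor:
        return ((v @ self.W1 + self.b1).relu() + self.b2) @ self.W2

    def __call__(self, x: Tensor) -> Tensor:
        """x: (B, m, F) -> weights (B, m) in (0, 1)."""
        mx = x.max(axis=2)
        avg = x.mean(axis=2)
        return (self._mlp(mx) + self._mlp(avg)).sigmoid()


def _compatible_reduction(m: int, r: int) -> int:
    """Largest divisor of m that is <= r (so the bottleneck dim is integral)."""
    for cand in range(min(r, m), 0, -1):
        if m % cand == 0:
            return cand
    return 1


# --------------------------------------------------------------------------
# the full model
# --------------------------------------------------------------------------

class CdomNet(Module):
    """Full model over window sequences; see the module docstring."""

    def __init__(self, config: ModelConfig, n_eeg_channels: int, n_bands: int,
                 n_peripheral: int, scatter: np.ndarray, seed: int = 0):
        super().__init__()
        self.config = config
        self.n_eeg = n_eeg_channels
        self.n_bands = n_bands
        self.n_per = n_peripheral
        if scatter.shape[0] != n_eeg_channels:
            raise ValueError("scatter matrix rows must equal EEG channel count")
        self.scatter = Tensor(scatter)  # (C, 81) 0/1 grid placement
        self.grid_hw = int(np.sqrt(scatter.shape[1]))
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x11]))
        self._rng = np.random.default_rng(np.random.SeedSequence([seed, 0x22]))
        # optional input standardization (fitted on the training partition)
        self.input_scaler: dict[str, tuple[np.ndarray, np.ndarray]] | None = None

        if config.use_channel_attention:
            self.ca_eeg = ChannelAttention(n_eeg_channels, config.reduction_ratio, rng)
            self.ca_per = ChannelAttention(n_peripheral, config.reduction_ratio, rng)
        self.cnn = DepthwiseSeparableCnn(n_bands, config.dsc, rng)
        flat = config.dsc.channels * scatter.shape[1]
        self.embed = Linear(flat, config.spatial_embed_dim, rng)
        per_feat = 0
        if config.use_peripheral_lstm:
            self.per_lstm = PlainLstm(1, config.peripheral_lstm_hidden, rng)
            per_feat += config.peripheral_lstm_hidden
        if config.use_peripheral_stats:
            per_feat += 5
        self.per_feat_dim = per_feat
        d_eeg = config.spatial_embed_dim
        d_per = per_feat * n_peripheral
        self.mod_score_eeg = Linear(d_eeg, 1, rng)
        self.mod_score_per = Linear(d_per, 1, rng)
        self.temporal = OnLstm(d_eeg + d_per, config.onlstm, rng,
                               master_open=config.standard_lstm)
        if config.use_mha:
            self.proj = Linear(self.temporal.out_dim, config.mha.hidden, rng)
            self.mha = MultiHeadAttention(config.mha, rng)
            head_in = config.mha.hidden
        else:
            head_in = self.temporal.out_dim
        self.heads = {dim: Linear(head_in, config.n_classes, rng)
                      for dim in config.label_dims}
        # expose head parameters to discovery
        self._head_list = list(self.heads.values())

    def seed_dropout(self, seed: int) -> None:
        self._rng = np.random.default_rng(np.random.SeedSequence([seed, 0x22]))

    # -- forward ----------------------------------------------------------
    def __call__(self, de: np.ndarray, per_pooled: np.ndarray,
                 per_stats: np.ndarray) -> dict:
        """Forward one batch of window sequences.

        de: (B, T, C, n_bands) channel-level DE values
        per_pooled: (B, T, l, T_p) time-pooled peripheral samples
        per_stats: (B, T, l, 5) peripheral statistics
        Returns a dict with per-dimension probabilities and the intermediate
        features the MI loss needs.
        """
        cfg = self.config
        B, T, C, nb = de.shape
        if C != self.n_eeg or nb != self.n_bands:
            raise ValueError(f"DE batch shape {de.shape} inconsistent with model "
                             f"({self.n_eeg} channels, {self.n_bands} bands)")
        if self.input_scaler is not None:
            mu, sd = self.input_scaler["de"]
            de = (de - mu) / sd
            mu, sd = self.input_scaler["per_stats"]
            per_stats = (per_stats - mu) / sd
            mu, sd = self.input_scaler["per_pooled"]
            per_pooled = (per_pooled - mu) / sd
        rng = self._rng
        de_t = Tensor(de.reshape(B * T, C, nb))

        if cfg.use_channel_attention:
            w_eeg = self.ca_eeg(de_t)  # (B*T, C)
            de_w = de_t * w_eeg.reshape(B * T, C, 1)
        else:
            w_eeg = None
            de_w = de_t
        # scatter channels onto the grid: (B*T, nb, C) @ (C, 81)
        grid = (de_w.swapaxes(1, 2) @ self.scatter).reshape(
            B * T, nb, self.grid_hw, self.grid_hw)
        f_eeg = self.embed(self.cnn(grid, rng))  # (B*T, d_eeg)

        per_parts = []
        if cfg.use_peripheral_lstm:
            l = self.n_per
            tp = per_pooled.shape[-1]
            seq = Tensor(per_pooled.reshape(B * T * l, tp, 1))
            h = self.per_lstm(seq).reshape(B * T, l, -1)
            per_parts.append(h)
        if cfg.use_peripheral_stats:
            per_parts.append(Tensor(per_stats.reshape(B * T, self.n_per, 5)))
        per_block = cat(per_parts, axis=-1)  # (B*T, l, per_feat)
        if cfg.use_channel_attention:
            w_per = self.ca_per(per_block)
            per_block = per_block * w_per.reshape(B * T, self.n_per, 1)
        else:
            w_per = None
        f_per = per_block.reshape(B * T, self.n_per * self.per_feat_dim)

        # modality weights: softmax over per-modality perceptron scores
        s_eeg = self.mod_score_eeg(f_eeg)
        s_per = self.mod_score_per(f_per)
        omega = cat([s_eeg, s_per], axis=-1).softmax(axis=-1)  # (B*T, 2)
        f_eeg_w = f_eeg * omega[:, 0:1]
        f_per_w = f_per * omega[:, 1:2]
        fused = cat([f_eeg_w, f_per_w], axis=-1)

        seq = fused.reshape(B, T, -1)
        oall, olast = self.temporal(seq, rng)
        if cfg.use_mha:
            feat = self.mha(self.proj(oall), self.proj(olast), rng)
        else:
            feat = olast.reshape(B, -1)

        probs = {dim: self.heads[dim](feat).softmax(axis=-1)
                 for dim in cfg.label_dims}
        return {
            "probs": probs,
            "fused": fused,
            "f_eeg": f_eeg_w,
            "f_per": f_per_w,
            "modality_weights": omega,
            "eeg_channel_weights": w_eeg,
            "peripheral_channel_weights": w_per,
        }

    def predict_proba(self, de, per_pooled, per_stats) -> dict[str, np.ndarray]:
        """Eval-mode class probabilities per label dimension."""
        was_training = self.training
        self.eval()
        try:
            with no_grad():
                out = self(de, per_pooled, per_stats)
        finally:
            if was_training:
                self.train()
        return {d: p.data.copy() for d, p in out["probs"].items()}


def forward(model: CdomNet, batch: dict) -> dict[str, np.ndarray]:
    """Functional wrapper: batch dict with 'de', 'per_pooled', 'per_stats'."""
    return model.predict_proba(batch["de"], batch["per_pooled"], batch["per_stats"])


# --------------------------------------------------------------------------
# checkpoints
# --------------------------------------------------------------------------

def save_checkpoint(model: CdomNet, path: str | Path, extra: dict | None = None) -> Path:
    """Parameters to .npz plus a JSON sidecar with the config embedded."""
    path = Path(path)
    arrays = {name: p.data for name, p in model.named_parameters()}
    arrays["__scatter__"] = model.scatter.data
    if model.input_scaler is not None:
        for key, (mu, sd) in model.input_scaler.items():
            arrays[f"__scaler__{key}__mu"] = mu
            arrays[f"__scaler__{key}__sd"] = sd
    np.savez(path, **arrays)
    meta = {
        "config": model.config.to_dict(),
        "n_eeg": model.n_eeg,
        "n_bands": model.n_bands,
        "n_peripheral": model.n_per,
    }
    if extra:
        meta["extra"] = extra
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    return path


def load_checkpoint(path: str | Path, seed: int = 0) -> CdomNet:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    data = np.load(path if path.suffix == ".npz" else path.with_suffix(".npz"))
    model = CdomNet(ModelConfig.from_dict(meta["config"]), meta["n_eeg"],
                    meta["n_bands"], meta["n_peripheral"],
                    scatter=data["__scatter__"], seed=seed)
    params = dict(model.named_parameters())
    for name, p in params.items():
        if name not in data:
            raise ValueError(f"checkpoint missing parameter {name}")
        p.data = data[name].copy()
    scaler = {}
    for key in ("de", "per_stats", "per_pooled"):
        if f"__scaler__{key}__mu" in data:
            scaler[key] = (data[f"__scaler__{key}__mu"], data[f"__scaler__{key}__sd"])
    model.input_scaler = scaler or None
    return model
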