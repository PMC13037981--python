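"""Combined loss, optimizer schedule, augmentation, and the training loop.

The objective is ``L = alpha * L_CE + beta * L_MI`` with alpha = 0.6 and
beta = 0.2 (kept verbatim; they do not sum to one).  L_CE is mean binary
cross-entropy in nats.  L_MI = -I(F_fusion; Y) + lambda * sum of pairwise
inter-modality MI with lambda = 0.1: it rewards fused features informative
about the labels and penalizes redundancy between modalities.

The histogram plug-in MI estimator is not differentiable, so during training
the MI term is evaluated through a Gaussian soft-binning relaxation of the
same per-dimension quantile binning (gradients reach the modality-weight
perceptron and everything upstream of it); the plug-in estimator remains the
canonical, testable definition and is what ``mi_loss`` computes by default.

Optimization: Adam (beta1 0.9, beta2 0.999, eps 1e-8), initial learning
rate 1e-4 decaying by 0.9 every 5 epochs, L2 weight decay 1e-4, batch 32,
early stopping on validation accuracy with patience 3, keeping the weights
of the best validation epoch.  Augmentation jitters each training window by
a circular time shift (within +/-0.1 s) and an amplitude scale in
[0.9, 1.1]; on the precomputed features this is applied in closed form
(DE shifts by ln s, statistics scale accordingly).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import mi
from .autograd import Tensor
from .data import FeatureDataset, SequenceIndex
from .network import CdomNet
from .preprocess import SignalWindow

__all__ = [
    "Adam",
    "LossConfig",
    "TrainConfig",
    "TrainingHistory",
    "augment",
    "augment_feature_batch",
    "cross_entropy",
    "fit",
    "lr_at",
    "mi_loss",
    "softbin_mi_label",
    "softbin_mi_pair",
    "total_loss",
]


@dataclass
class LossConfig:
    alpha: float = 0.6   # weight of the cross-entropy term
    beta: float = 0.2    # weight of the mutual-information term
    lam: float = 0.1     # redundancy penalty inside the MI term
    mi_estimator: str = "softbin"  # "softbin" (differentiable) or "hist"
    n_bins: int = mi.DEFAULT_BINS
    mi_max_dims: int = 16  # feature dims sampled (evenly strided) for MI

    def __post_init__(self) -> None:
        if min(self.alpha, self.beta, self.lam) < 0:
            raise ValueError("loss weights must be non-negative")


@dataclass
class TrainConfig:
    batch_size: int = 32
    max_epochs: int = 100
    patience: int = 3
    lr: float = 1e-4
    lr_decay: float = 0.9
    lr_decay_every: int = 5
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    weight_decay: float = 1e-4
    time_shift_s: float = 0.1
    amp_scale: tuple[float, float] = (0.9, 1.1)
    augment: bool = True
    seed: int = 0


# --------------------------------------------------------------------------
# loss pieces
# --------------------------------------------------------------------------

def cross_entropy(y_true: np.ndarray, y_prob: np.ndarray) -> float:
    """Mean binary cross-entropy in nats, probabilities clipped at 1e-12."""
    y = np.asarray(y_true, dtype=np.float64).ravel()
    p = np.asarray(y_prob, dtype=np.float64).ravel()
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {p.shape}")
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).mean())


def _ce_tensor(probs: Tensor, labels: np.ndarray) -> Tensor:
    """Differentiable mean CE from a (B, 2) probability tensor."""
    onehot = np.zeros(probs.shape)
    onehot[np.arange(len(labels)), np.asarray(labels, dtype=int)] = 1.0
    eps = 1e-12
    return -((Tensor(onehot) * (probs + eps).log()).sum(axis=-1)).mean()


def total_loss(ce: float, mi_value: float, cfg: LossConfig) -> float:
    """alpha * CE + beta * MI, verbatim weights."""
    return cfg.alpha * ce + cfg.beta * mi_value


def mi_loss(fused: np.ndarray, modality_features: Sequence[np.ndarray],
            labels: np.ndarray, cfg: LossConfig | None = None) -> float:
    """-I(fused; labels) + lambda * sum over modality pairs of I(Fm1; Fm2)."""
    cfg = cfg or LossConfig()
    if len(modality_features) < 2:
        raise ValueError("at least two modalities required")
    term = -mi.feature_label_mi(fused, labels, cfg.n_bins)
    for a in range(len(modality_features)):
        for b in range(a + 1, len(modality_features)):
            term += cfg.lam * mi.pairwise_feature_mi(
                modality_features[a], modality_features[b], cfg.n_bins)
    return float(term)


def lr_at(epoch: int, cfg: TrainConfig) -> float:
    """Step-decay schedule: lr0 * decay ** floor(epoch / every)."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    return cfg.lr * cfg.lr_decay ** (epoch // cfg.lr_decay_every)


# --------------------------------------------------------------------------
# differentiable soft-binning MI
# --------------------------------------------------------------------------

def _soft_assign(col: Tensor, centers: np.ndarray, tau: float) -> Tensor:
    """(n,) feature column -> (n, K) soft bin memberships (rows sum to 1)."""
    c = Tensor(centers[None, :])
    z = col.reshape(-1, 1) - c
    return (-(z * z) * (1.0 / (2.0 * tau * tau))).softmax(axis=-1)


def _bin_centers(x: np.ndarray, n_bins: int) -> tuple[np.ndarray, float]:
    qs = np.quantile(x, (np.arange(n_bins) + 0.5) / n_bins)
    span = x.max() - x.min()
    tau = max(span / n_bins, 1e-6)
    return qs, tau


def _dim_subset(d: int, max_dims: int) -> np.ndarray:
    if d <= max_dims:
        return np.arange(d)
    return np.unique(np.linspace(0, d - 1, max_dims).astype(int))


def softbin_mi_label(features: Tensor, labels: np.ndarray, n_bins: int = 16,
                     max_dims: int = 16) -> Tensor:
    """Differentiable MI between features and discrete labels, nats."""
    y = np.asarray(labels, dtype=int).ravel()
    classes, counts = np.unique(y, return_counts=True)
    py = counts / counts.sum()
    n, d = features.shape
    dims = _dim_subset(d, max_dims)
    total = None
    eps = 1e-12
    for j in dims:
        col_data = features.data[:, j]
        if np.ptp(col_data) < 1e-12:
            continue  # constant dim carries no information
        centers, tau = _bin_centers(col_data, n_bins)
        A = _soft_assign(features[:, j], centers, tau)  # (n, K)
        pk = A.mean(axis=0)  # (K,)
        term = None
        for c, pc in zip(classes, py):
            mask = Tensor((y == c).astype(float)[:, None])
            joint = (A * mask).mean(axis=0)  # (K,) = p(k, y=c)
            contrib = (joint * ((joint + eps).log() - (pk + eps).log()
                                - float(np.log(pc + eps)))).sum()
            term = contrib if term is None else term + contrib
        total = term if total is None else total + term
    if total is None:
        return Tensor(0.0)
    return total * (1.0 / len(dims))


def softbin_mi_pair(fa: Tensor, fb: Tensor, n_bins: int = 16,
                    max_dims: int = 16) -> Tensor:
    """Differentiable MI between two feature sets, index-paired dimensions."""
    da, db = fa.shape[1], fb.shape[1]
    dims = _dim_subset(max(da, db), max_dims)
    eps = 1e-12
    n = fa.shape[0]
    total = None
    used = 0
    for j in dims:
        ca, cb = fa.data[:, j % da], fb.data[:, j % db]
        if np.ptp(ca) < 1e-12 or np.ptp(cb) < 1e-12:
            continue
        cen_a, tau_a = _bin_centers(ca, n_bins)
        cen_b, tau_b = _bin_centers(cb, n_bins)
        A = _soft_assign(fa[:, j % da], cen_a, tau_a)
        B = _soft_assign(fb[:, j % db], cen_b, tau_b)
        joint = (A.swapaxes(0, 1) @ B) * (1.0 / n)  # (Ka, Kb)
        pa = joint.sum(axis=1, keepdims=True)
        pb = joint.sum(axis=0, keepdims=True)
        contrib = (joint * ((joint + eps).log() - (pa + eps).log()
                            - (pb + eps).log())).sum()
        total = contrib if total is None else total + contrib
        used += 1
    if total is None:
        return Tensor(0.0)
    return total * (1.0 / used)


def _mi_term(out: dict, labels_per_dim: np.ndarray, cfg: LossConfig) -> Tensor | float:
    """The MI loss on a forward pass's intermediates (estimator-dependent)."""
    labels_per_dim = np.asarray(labels_per_dim).ravel()
    n = out["fused"].shape[0]
    if n != labels_per_dim.size:  # features are per window, labels per sequence
        labels_per_dim = np.repeat(labels_per_dim, n // labels_per_dim.size)
    if cfg.mi_estimator == "hist":
        return mi_loss(out["fused"].data, [out["f_eeg"].data, out["f_per"].data],
                       labels_per_dim, cfg)
    label_mi = softbin_mi_label(out["fused"], labels_per_dim,
                                cfg.n_bins, cfg.mi_max_dims)
    pair = softbin_mi_pair(out["f_eeg"], out["f_per"], cfg.n_bins, cfg.mi_max_dims)
    return -label_mi + cfg.lam * pair


# --------------------------------------------------------------------------
# augmentation
# --------------------------------------------------------------------------

def augment(window: SignalWindow, cfg: TrainConfig,
            rng: np.random.Generator) -> SignalWindow:
    """Raw-window augmentation: circular time shift and amplitude scaling."""
    max_shift = int(cfg.time_shift_s * window.sampling_rate)
    shift = int(rng.integers(-max_shift, max_shift + 1)) if max_shift else 0
    scale = float(rng.uniform(*cfg.amp_scale))
    return SignalWindow(
        subject_id=window.subject_id, trial_id=window.trial_id,
        window_index=window.window_index, start_sample=window.start_sample,
        eeg=scale * np.roll(window.eeg, shift, axis=-1),
        peripheral=scale * np.roll(window.peripheral, shift, axis=-1),
        labels=dict(window.labels), sampling_rate=window.sampling_rate,
        eeg_channel_names=window.eeg_channel_names,
        peripheral_channel_names=window.peripheral_channel_names,
    )


def augment_feature_batch(batch: dict, cfg: TrainConfig,
                          rng: np.random.Generator) -> dict:
    """Closed-form image of the raw augmentation on precomputed features.

    Scaling a window by s multiplies its variance by s^2, so every DE cell
    shifts by ln s; mean/SD/peak scale by s while skewness and excess
    kurtosis are scale-invariant; the pooled peripheral trace is scaled and
    circularly rolled (the circular shift leaves window variance, and hence
    DE and the statistics, unchanged up to pooling granularity).
    """
    B = batch["de"].shape[0]
    scale = rng.uniform(*cfg.amp_scale, size=B)
    out = dict(batch)
    out["de"] = batch["de"] + np.log(scale)[:, None, None, None]
    stats = batch["per_stats"].copy()
    stats[..., :3] *= scale[:, None, None, None]  # mean, sd, peak
    out["per_stats"] = stats
    pooled = batch["per_pooled"] * scale[:, None, None, None]
    tp = pooled.shape[-1]
    max_shift = max(int(round(cfg.time_shift_s * tp / 3.0)), 0)  # 3 s window
    if max_shift:
        shifts = rng.integers(-max_shift, max_shift + 1, size=B)
        for i, s in enumerate(shifts):
            pooled[i] = np.roll(pooled[i], int(s), axis=-1)
    out["per_pooled"] = pooled
    return out


# --------------------------------------------------------------------------
# optimizer
# --------------------------------------------------------------------------

class Adam:
    """Adam with classic L2 weight decay added to the gradient."""

    def __init__(self, params: Sequence[Tensor], cfg: TrainConfig):
        self.params = list(params)
        self.cfg = cfg
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self, lr: float) -> None:
        c = self.cfg
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad + c.weight_decay * p.data
            self.m[i] = c.beta1 * self.m[i] + (1 - c.beta1) * g
            self.v[i] = c.beta2 * self.v[i] + (1 - c.beta2) * g * g
            mhat = self.m[i] / (1 - c.beta1 ** self.t)
            vhat = self.v[i] / (1 - c.beta2 ** self.t)
            p.data = p.data - lr * mhat / (np.sqrt(vhat) + c.eps)


# --------------------------------------------------------------------------
# the fit loop
# --------------------------------------------------------------------------

@dataclass
class TrainingHistory:
    epoch: list[int] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    train_ce: list[float] = field(default_factory=list)
    train_mi: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {k: list(v) for k, v in self.__dict__.items()}


def _accuracy(model: CdomNet, ds: FeatureDataset, seqs: SequenceIndex,
              batch_size: int = 128) -> float:
    """Mean over label dimensions of sequence-level accuracy."""
    correct = 0
    total = 0
    for lo in range(0, len(seqs), batch_size):
        idx = np.arange(lo, min(lo + batch_size, len(seqs)))
        b = seqs.batch(ds, idx)
        probs = model.predict_proba(b["de"], b["per_pooled"], b["per_stats"])
        for d, dim in enumerate(ds.label_dims):
            pred = probs[dim].argmax(axis=1)
            correct += int((pred == b["labels"][:, d]).sum())
            total += len(idx)
    return correct / total


def fit(model: CdomNet, ds: FeatureDataset, train_seqs: SequenceIndex,
        val_seqs: SequenceIndex, train_cfg: TrainConfig | None = None,
        loss_cfg: LossConfig | None = None,
        verbose: bool = False) -> tuple[CdomNet, TrainingHistory]:
    """Train with Adam + early stopping; returns the best-validation model.

    Fully seeded via ``train_cfg.seed``: shuffling, dropout, and
    augmentation draws all derive from it.
    """
    train_cfg = train_cfg or TrainConfig()
    loss_cfg = loss_cfg or LossConfig()
    if len(train_seqs) == 0 or len(val_seqs) == 0:
        raise ValueError("train and validation partitions must be non-empty")
    ss = np.random.SeedSequence([train_cfg.seed, 0x7EA1])
    shuffle_rng, aug_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    model.seed_dropout(train_cfg.seed)
    opt = Adam(model.parameters(), train_cfg)
    hist = TrainingHistory()
    best_acc = -np.inf
    best_state = None
    stale = 0

    for epoch in range(train_cfg.max_epochs):
        lr = lr_at(epoch, train_cfg)
        model.train()
        order = shuffle_rng.permutation(len(train_seqs))
        ce_sum = mi_sum = loss_sum = 0.0
        n_batches = 0
        for lo in range(0, len(order), train_cfg.batch_size):
            idx = order[lo: lo + train_cfg.batch_size]
            batch = train_seqs.batch(ds, idx)
            if train_cfg.augment:
                batch = augment_feature_batch(batch, train_cfg, aug_rng)
            out = model(batch["de"], batch["per_pooled"], batch["per_stats"])
            ce = None
            for d, dim in enumerate(ds.label_dims):
                term = _ce_tensor(out["probs"][dim], batch["labels"][:, d])
                ce = term if ce is None else ce + term
            ce = ce * (1.0 / len(ds.label_dims))
            mi_term = _mi_term(out, batch["labels"][:, 0], loss_cfg)
            if isinstance(mi_term, Tensor):
                loss = loss_cfg.alpha * ce + loss_cfg.beta * mi_term
                mi_val = float(mi_term.data)
            else:
                loss = loss_cfg.alpha * ce + Tensor(loss_cfg.beta * mi_term)
                mi_val = float(mi_term)
            model.zero_grad()
            loss.backward()
            opt.step(lr)
            ce_sum += float(ce.data)
            mi_sum += mi_val
            loss_sum += float(loss.data)
            n_batches += 1
        model.eval()
        val_acc = _accuracy(model, ds, val_seqs)
        hist.epoch.append(epoch)
        hist.lr.append(lr)
        hist.train_loss.append(loss_sum / n_batches)
        hist.train_ce.append(ce_sum / n_batches)
        hist.train_mi.append(mi_sum / n_batches)
        hist.val_accuracy.append(val_acc)
        if verbose:
            print(f"epoch {epoch:3d} lr {lr:.2e} loss {loss_sum / n_batches:.4f} "
                  f"val_acc {val_acc:.4f}")
        if val_acc > best_acc:
            best_acc = val_acc
            best_state = {name: p.data.copy() for name, p in model.named_parameters()}
            stale = 0
        else:
            stale += 1
            if stale >= train_cfg.patience:
                break
    if best_state is not None:
        for name, p in model.named_parameters():
            p.data = best_state[name]
    model.eval()
    return model, hist
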