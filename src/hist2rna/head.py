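"""The aggregation-based regression head: 1D convolutions over the feature axis.

One aggregated slide-level vector (length F) is treated as a 1-channel
sequence and passed through three 1D convolutional blocks — C1 with 256
kernels of size 5, C2 and C3 with 512 kernels of size 1, each ReLU-activated —
followed by global average pooling and a linear output layer with one neuron
per target gene (default 138).  Training uses Adam on mean-squared error with
minibatches of 12, early stopping with patience 4 on a held-out validation
split, and a cap of 150 epochs; the weights from the best monitored epoch are
restored.

The network, its gradients and the optimiser are implemented directly in
NumPy: the model is a few dense matrix products, so no deep-learning framework
is required, and every arithmetic step is visible and testable.
"""

from __future__ import annotations

import copy
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from ._errors import AlignmentError, ConfigurationError, InvalidInputError, StateError
from .expression import ExpressionMatrix
from .features import AggregatedFeature

__all__ = [
    "HeadConfig",
    "TrainConfig",
    "TrainedHead",
    "build_head",
    "train_head",
    "train_on_matrix",
    "predict",
    "predict_matrix",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HeadConfig:
    """Architecture of the convolutional regression head."""

    conv_channels: tuple[int, ...] = (256, 512, 512)
    kernel_sizes: tuple[int, ...] = (5, 1, 1)
    output_dim: int = 138
    ordering_variant: str = "pool_then_dense"  # or "conv_out_then_pool"

    def __post_init__(self) -> None:
        if len(self.conv_channels) != len(self.kernel_sizes):
            raise ConfigurationError("conv_channels and kernel_sizes must have equal length")
        if self.output_dim < 1:
            raise ConfigurationError("output_dim must be >= 1")
        if self.ordering_variant not in ("pool_then_dense", "conv_out_then_pool"):
            raise ConfigurationError(f"unknown ordering_variant {self.ordering_variant!r}")
        if any(k < 1 for k in self.kernel_sizes) or any(c < 1 for c in self.conv_channels):
            raise ConfigurationError("kernel sizes and channel counts must be >= 1")


@dataclass(frozen=True)
class TrainConfig:
    """The training recipe: Adam, MSE, minibatch 12, early stopping patience 4."""

    learning_rate: float = 0.001
    batch_size: int = 12
    early_stop_patience: int = 4
    max_epochs: int = 150
    validation_fraction: float = 0.1
    monitor: str = "val"  # or "train"
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be >= 1")
        if not 0.0 <= self.validation_fraction < 1.0:
            raise ConfigurationError("validation_fraction must be in [0, 1)")
        if self.monitor not in ("val", "train"):
            raise ConfigurationError(f"monitor must be 'val' or 'train', got {self.monitor!r}")


class _Model:
    """Parameter container: conv layers then either dense-out or conv-out."""

    def __init__(self, head_cfg: HeadConfig, input_dim: int, rng: np.random.Generator,
                 dtype=np.float32, output_bias_init: np.ndarray | None = None):
        if input_dim < head_cfg.kernel_sizes[0]:
            raise ConfigurationError(
                f"input dimension {input_dim} is smaller than the first kernel size "
                f"{head_cfg.kernel_sizes[0]}"
            )
        self.config = head_cfg
        self.input_dim = input_dim
        self.dtype = np.dtype(dtype)
        self.conv_W: list[np.ndarray] = []
        self.conv_b: list[np.ndarray] = []
        c_in, length = 1, input_dim
        for c_out, k in zip(head_cfg.conv_channels, head_cfg.kernel_sizes):
            if length < k:
                raise ConfigurationError("sequence shorter than kernel size in conv stack")
            fan_in = c_in * k
            w = rng.standard_normal((fan_in, c_out)) * np.sqrt(2.0 / fan_in)  # He (ReLU)
            self.conv_W.append(w.astype(self.dtype))
            self.conv_b.append(np.zeros(c_out, dtype=self.dtype))
            c_in, length = c_out, length - k + 1
        self.seq_len = length
        g = head_cfg.output_dim
        fan_in = c_in
        limit = np.sqrt(6.0 / (fan_in + g))  # Glorot (linear output)
        self.out_W = (rng.uniform(-limit, limit, size=(fan_in, g))).astype(self.dtype)
        self.out_b = np.zeros(g, dtype=self.dtype)
        if output_bias_init is not None:
            self.out_b = np.asarray(output_bias_init, dtype=self.dtype).copy()

    def parameters(self) -> list[np.ndarray]:
        return [*self.conv_W, *self.conv_b, self.out_W, self.out_b]

    def set_parameters(self, params: list[np.ndarray]) -> None:
        n = len(self.conv_W)
        self.conv_W = [p.copy() for p in params[:n]]
        self.conv_b = [p.copy() for p in params[n : 2 * n]]
        self.out_W = params[2 * n].copy()
        self.out_b = params[2 * n + 1].copy()

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def forward(self, X: np.ndarray, cache: list | None = None) -> np.ndarray:
        """X: (B, F) -> (B, output_dim).  If cache given, store activations."""
        h = np.ascontiguousarray(X, dtype=self.dtype)[:, :, None]  # (B, L, 1)
        if cache is not None:
            cache.append(h)
        for w, b, k in zip(self.conv_W, self.conv_b, self.config.kernel_sizes):
            if k == 1:
                pre = h @ w.reshape(h.shape[2], -1) + b
            else:
                win = np.lib.stride_tricks.sliding_window_view(h, k, axis=1)  # (B,L',C,k)
                win = win.reshape(win.shape[0], win.shape[1], -1)  # (B, L', C*k)
                pre = win @ w + b
                if cache is not None:
                    cache.append(("win", win))
            h = np.maximum(pre, 0.0)
            if cache is not None:
                cache.append(("act", pre > 0, h))
        if self.config.ordering_variant == "pool_then_dense":
            pooled = h.mean(axis=1)  # (B, C)
            if cache is not None:
                cache.append(("pooled", pooled, h.shape[1]))
            return pooled @ self.out_W + self.out_b
        # conv_out_then_pool: linear 1x1 conv to output_dim channels, then pool
        pre_out = h @ self.out_W + self.out_b  # (B, L', G)
        if cache is not None:
            cache.append(("preout", h, pre_out.shape[1]))
        return pre_out.mean(axis=1)

    def backward(self, cache: list, dpred: np.ndarray) -> list[np.ndarray]:
        """Gradient of the scalar loss w.r.t. every parameter (same order as parameters())."""
        dconv_W = [None] * len(self.conv_W)
        dconv_b = [None] * len(self.conv_b)
        i = len(cache) - 1
        if self.config.ordering_variant == "pool_then_dense":
            tag, pooled, seq_len = cache[i]
            i -= 1
            d_out_W = pooled.T @ dpred
            d_out_b = dpred.sum(axis=0)
            dh = (dpred @ self.out_W.T)[:, None, :] / seq_len
            dh = np.broadcast_to(dh, (dpred.shape[0], seq_len, self.out_W.shape[0])).copy()
        else:
            tag, h_last, seq_len = cache[i]
            i -= 1
            dpre_out = np.broadcast_to(dpred[:, None, :] / seq_len,
                                       (dpred.shape[0], seq_len, dpred.shape[1]))
            d_out_W = h_last.reshape(-1, h_last.shape[2]).T @ dpre_out.reshape(-1, dpred.shape[1])
            d_out_b = dpre_out.sum(axis=(0, 1))
            dh = dpre_out @ self.out_W.T
        for layer in range(len(self.conv_W) - 1, -1, -1):
            tag, relu_mask, _h = cache[i]
            i -= 1
            da = dh * relu_mask
            k = self.config.kernel_sizes[layer]
            if k == 1:
                prev = cache[i][2] if isinstance(cache[i], tuple) else cache[i]
                c_in = self.conv_W[layer].shape[0]
                dconv_W[layer] = (prev.reshape(-1, c_in).T @ da.reshape(-1, da.shape[2]))
                dconv_b[layer] = da.sum(axis=(0, 1))
                dh = da @ self.conv_W[layer].T
            else:
                tag2, win = cache[i]
                i -= 1
                fan_in = self.conv_W[layer].shape[0]
                c_in = fan_in // k
                dconv_W[layer] = win.reshape(-1, fan_in).T @ da.reshape(-1, da.shape[2])
                dconv_b[layer] = da.sum(axis=(0, 1))
                if layer == 0:
                    dh = None  # input gradient not needed
                else:
                    b_sz, l_out = da.shape[0], da.shape[1]
                    dwin = (da @ self.conv_W[layer].T).reshape(b_sz, l_out, c_in, k)
                    dh = np.zeros((b_sz, l_out + k - 1, c_in), dtype=da.dtype)
                    for j in range(k):  # scatter window gradients back onto the sequence
                        dh[:, j : j + l_out, :] += dwin[:, :, :, j]
        return [*dconv_W, *dconv_b, d_out_W, d_out_b]


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            g = g.astype(p.dtype)
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


@dataclass
class TrainedHead:
    """A trained head with its configuration, weights and training history."""

    head_config: HeadConfig
    train_config: TrainConfig
    input_dim: int
    model: _Model = field(repr=False)
    history: dict = field(repr=False)
    best_epoch: int
    samples_seen_per_epoch: list[int] = field(default_factory=list, repr=False)

    @property
    def monitored_history(self) -> list[float]:
        key = "val_loss" if self.train_config.monitor == "val" and self.history["val_loss"] else "train_loss"
        return self.history[key]

    @property
    def total_samples_seen(self) -> int:
        return int(sum(self.samples_seen_per_epoch))


def build_head(config: HeadConfig, input_dim: int, seed: int = 0,
               dtype: str = "float32") -> _Model:
    """Instantiate the head for feature dimension F; errors if F < first kernel size."""
    rng = np.random.default_rng(seed)
    return _Model(config, input_dim, rng, dtype=np.dtype(dtype))


def _mse(pred: np.ndarray, y: np.ndarray) -> float:
    d = pred - y
    return float(np.mean(d * d))


def train_on_matrix(
    X: np.ndarray,
    Y: np.ndarray,
    train_cfg: TrainConfig,
    head_cfg: HeadConfig | None = None,
) -> TrainedHead:
    """Train the head on an (n_samples, F) design against (n_samples, G) targets.

    The per-epoch training loss recorded in the history is the loss over the
    full training split evaluated after the epoch's updates (a deterministic
    series, suitable for patience-based stopping); validation loss is computed
    on the held-out split after each epoch.  The weights of the best monitored
    epoch are restored at the end.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
        raise InvalidInputError(f"incompatible design {X.shape} and target {Y.shape} shapes")
    n = X.shape[0]
    if head_cfg is None:
        head_cfg = HeadConfig(output_dim=Y.shape[1])
    if head_cfg.output_dim != Y.shape[1]:
        raise ConfigurationError(
            f"head output_dim {head_cfg.output_dim} != target width {Y.shape[1]}"
        )
    rng = np.random.default_rng(train_cfg.seed)
    perm = rng.permutation(n)
    n_val = int(round(train_cfg.validation_fraction * n))
    if train_cfg.monitor == "val" and n_val == 0:
        warnings.warn("validation fraction yields 0 samples; monitoring training loss",
                      stacklevel=2)
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    if train_idx.size == 0:
        raise InvalidInputError("no training samples left after validation split")
    batch = train_cfg.batch_size
    if batch > train_idx.size:
        warnings.warn(
            f"batch size {batch} exceeds {train_idx.size} training samples; "
            "falling back to full-batch updates", stacklevel=2)
        batch = train_idx.size

    model = _Model(head_cfg, X.shape[1], rng, dtype=np.dtype(train_cfg.dtype),
                   output_bias_init=Y[train_idx].mean(axis=0))
    opt = _Adam(model.parameters(), train_cfg.learning_rate)
    Xtr, Ytr = X[train_idx], Y[train_idx]
    Xva, Yva = X[val_idx], Y[val_idx]
    monitor_val = train_cfg.monitor == "val" and n_val > 0

    history = {"train_loss": [], "val_loss": []}
    samples_seen: list[int] = []
    best_loss, best_params, best_epoch, wait = np.inf, None, 0, 0
    for epoch in range(1, train_cfg.max_epochs + 1):
        order = rng.permutation(train_idx.size)
        for start in range(0, train_idx.size, batch):
            sel = order[start : start + batch]
            xb, yb = Xtr[sel], Ytr[sel]
            cache: list = []
            pred = model.forward(xb, cache)
            yb = yb.astype(pred.dtype)
            dpred = (2.0 / pred.size) * (pred - yb)
            grads = model.backward(cache, dpred)
            params = model.parameters()
            opt.step(params, grads)
            model.set_parameters(params)
        train_loss = _mse(model.forward(Xtr), Ytr.astype(model.dtype))
        history["train_loss"].append(train_loss)
        if n_val > 0:
            history["val_loss"].append(_mse(model.forward(Xva), Yva.astype(model.dtype)))
        samples_seen.append(int(train_idx.size))
        monitored = history["val_loss"][-1] if monitor_val else train_loss
        if monitored < best_loss:
            best_loss, best_epoch, wait = monitored, epoch, 0
            best_params = [p.copy() for p in model.parameters()]
        else:
            wait += 1
            if wait >= train_cfg.early_stop_patience:
                logger.info("early stopping at epoch %d (best epoch %d)", epoch, best_epoch)
                break
    if best_params is not None:
        model.set_parameters(best_params)
    return TrainedHead(
        head_config=head_cfg,
        train_config=train_cfg,
        input_dim=X.shape[1],
        model=model,
        history=history,
        best_epoch=best_epoch,
        samples_seen_per_epoch=samples_seen,
    )


def _align(features, targets: ExpressionMatrix) -> tuple[np.ndarray, np.ndarray, list[str]]:
    feats = {f.patient_id: f.values for f in features}
    missing = [p for p in targets.patient_ids if p not in feats]
    extra = [p for p in feats if p not in set(targets.patient_ids)]
    if missing or extra:
        raise AlignmentError(
            f"patient mismatch between features and targets: "
            f"missing features for {missing[:5]}, targets absent for {extra[:5]}"
        )
    ids = list(targets.patient_ids)
    X = np.stack([feats[p] for p in ids])
    return X, targets.values, ids


def train_head(
    features,
    targets: ExpressionMatrix,
    train_cfg: TrainConfig = TrainConfig(),
    head_cfg: HeadConfig | None = None,
) -> TrainedHead:
    """Train on one aggregated feature vector per patient (the efficient route).

    ``features`` is a collection of :class:`AggregatedFeature`; targets must be
    on the log2(1+x) scale and cover exactly the same patients.
    """
    if targets.scale != "log2p1":
        raise StateError("targets must be log2(1+x)-transformed before training")
    X, Y, _ = _align(features, targets)
    return train_on_matrix(X, Y, train_cfg, head_cfg)


def predict(model: TrainedHead, features: AggregatedFeature) -> np.ndarray:
    """Predict the gene vector for one patient's aggregated feature."""
    v = np.asarray(features.values, dtype=float)
    if v.size != model.input_dim:
        raise InvalidInputError(f"feature length {v.size} != training dimension {model.input_dim}")
    return model.model.forward(v[None, :])[0]


def predict_matrix(model: TrainedHead, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.input_dim:
        raise InvalidInputError(f"design shape {X.shape} != (*, {model.input_dim})")
    return model.model.forward(X)
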