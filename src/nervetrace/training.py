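"""Training loop: Adam on binary cross-entropy, fixed epoch count.

The epoch budget and batching mirror the study protocol: the training and
validation sets are divided into a fixed number of mini-batches (five by
default, batch size = ceil(n / n_batches), last batch smaller) and training
runs for a fixed 20 epochs with Adam -- no early stopping, no schedule.
Every random draw (shuffling) comes from the config seed; weight
initialisation is seeded by the model config, so a run is reproducible
end to end on one platform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DivergenceError, GeometryError
from .nn import Adam
from .segnets import SegModel

__all__ = ["TrainConfig", "LossHistory", "bce_loss", "bce_grad", "train"]

BCE_EPS = 1e-7


@dataclass
class TrainConfig:
    epochs: int = 20
    n_batches: int = 5
    batch_size: int | None = None  # overrides n_batches when set
    learning_rate: float = 1e-3
    betas: tuple[float, float] = (0.9, 0.999)
    adam_eps: float = 1e-7
    clip_norm: float | None = None  # global gradient-norm clipping
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise ConfigurationError("epochs must be >= 1")
        if self.batch_size is None and self.n_batches < 1:
            raise ConfigurationError("n_batches must be >= 1")
        if self.batch_size is not None and self.batch_size < 1:
            raise ConfigurationError("batch_size must be >= 1")


@dataclass
class LossHistory:
    """Per-epoch mean training and validation loss."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)

    def __len__(self):
        return len(self.train_loss)


def bce_loss(probabilities: np.ndarray, mask, eps: float = BCE_EPS) -> float:
    """Mean binary cross-entropy over pixels.

    ``-(y log p + (1-y) log(1-p))`` averaged over all pixels, with the
    probabilities clipped into [eps, 1-eps] to avoid log(0).
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(getattr(mask, "pixels", mask), dtype=float)
    if p.shape != y.shape:
        raise GeometryError(f"shape mismatch {p.shape} vs {y.shape}")
    p = np.clip(p, eps, 1.0 - eps)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log1p(-p)))


def bce_grad(probabilities: np.ndarray, mask, eps: float = BCE_EPS) -> np.ndarray:
    """Gradient of :func:`bce_loss` with respect to the probabilities."""
    p = np.clip(np.asarray(probabilities), eps, 1.0 - eps)
    y = np.asarray(getattr(mask, "pixels", mask), dtype=p.dtype)
    return ((p - y) / (p * (1.0 - p)) / p.size).astype(p.dtype)


def _clip_gradients(params, max_norm: float) -> None:
    """Scale all gradients so their global L2 norm is at most ``max_norm``."""
    total = math.sqrt(sum(float((p.grad ** 2).sum()) for p in params))
    if total > max_norm:
        scale = max_norm / total
        for p in params:
            p.grad *= scale


def _to_tensors(pairs, dtype):
    """Stack (frame, mask) pairs into NHWC float inputs and targets."""
    xs, ys = [], []
    for frame, mask in pairs:
        f = np.asarray(getattr(frame, "pixels", frame)).astype(dtype)
        if f.max() > 1.0:
            f = f / 255.0
        xs.append(f[:, :, None])
        ys.append(np.asarray(getattr(mask, "pixels", mask),
                             dtype=dtype)[:, :, None])
    return np.stack(xs), np.stack(ys)


def _batches(order: np.ndarray, batch_size: int):
    for i in range(0, order.size, batch_size):
        yield order[i:i + batch_size]


def train(model: SegModel, train_pairs, val_pairs,
          config: TrainConfig | None = None) -> tuple[SegModel, LossHistory]:
    """Train ``model`` in place; returns it with the per-epoch loss history.

    Training loss per epoch is the pixel-weighted mean over batches (so it
    equals the dataset mean regardless of shuffling); validation loss is
    computed with no weight updates.  A non-finite loss raises
    :class:`DivergenceError` naming the epoch.
    """
    config = config or TrainConfig()
    if not train_pairs:
        raise ConfigurationError("empty training set")
    n = len(train_pairs)
    if config.batch_size is not None:
        bs = config.batch_size
    else:
        if config.n_batches > n:
            raise ConfigurationError(
                f"n_batches {config.n_batches} exceeds dataset size {n}")
        bs = math.ceil(n / config.n_batches)

    dtype = model.config.dtype
    x_tr, y_tr = _to_tensors(train_pairs, dtype)
    x_va, y_va = _to_tensors(val_pairs, dtype) if val_pairs else (None, None)

    opt = Adam(model.parameters(), lr=config.learning_rate,
               betas=config.betas, eps=config.adam_eps)
    rng = np.random.default_rng(config.seed)
    history = LossHistory()

    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(n)
        total = 0.0
        for idx in _batches(order, bs):
            xb, yb = x_tr[idx], y_tr[idx]
            prob = model.forward(xb)
            loss = bce_loss(prob, yb)
            if not np.isfinite(loss):
                raise DivergenceError(epoch)
            total += loss * idx.size
            opt.zero_grad()
            model.backward(bce_grad(prob, yb))
            if config.clip_norm is not None:
                _clip_gradients(model.parameters(), config.clip_norm)
            opt.step()
        history.train_loss.append(total / n)

        if x_va is not None:
            vtotal = 0.0
            for idx in _batches(np.arange(x_va.shape[0]), bs):
                vtotal += bce_loss(model.forward(x_va[idx]), y_va[idx]) * idx.size
            vloss = vtotal / x_va.shape[0]
            if not np.isfinite(vloss):
                raise DivergenceError(epoch)
            history.val_loss.append(vloss)

    return model, history
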