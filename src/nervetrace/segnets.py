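"""U-Net and SegNet encoder-decoder architectures for nerve segmentation.

Both networks share the same encoder shape: ``depth`` stages of two 3x3
same-padding convolutions (ReLU) followed by 2x2 max-pooling, with channel
widths doubling per stage from ``base_channels``.  At the default
configuration (256x256 input, depth 5) the bottleneck feature map is 8x8.

They differ only in how the decoder returns to full resolution:

* **U-Net** upsamples with learned 2x2 stride-2 transposed convolutions and
  concatenates the matching encoder feature map (skip connection) before each
  decoder convolution block.
* **SegNet** upsamples by index unpooling -- values are routed back to the
  argmax positions recorded by the encoder's max-pooling -- with no skip
  concatenation and no learned upsampling, which is why it has strictly
  fewer trainable parameters at equal configuration.

A final 1x1 convolution and logistic head map the last feature map to a
per-pixel foreground probability in (0, 1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .errors import ConfigurationError, GeometryError

__all__ = [
    "SegModelConfig",
    "SegModel",
    "UNet",
    "SegNet",
    "build_unet",
    "build_segnet",
    "predict_mask",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class SegModelConfig:
    """Configuration shared by both architectures.

    Parameters
    ----------
    architecture : {"unet", "segnet"}
    input_size : int
        Square input side in pixels; must be divisible by ``2**depth``.
    depth : int
        Number of pooling stages.  256 input with depth 5 bottoms out at 8x8.
    base_channels : int
        Channel width of the first encoder stage; doubles per stage.
    seed : int
        Seeds the weight initialisation.
    dtype : numpy dtype
        float32 by default; float64 available for gradient checking.
    """

    architecture: str = "unet"
    input_size: int = 256
    depth: int = 5
    base_channels: int = 16
    seed: int = 0
    dtype: type = field(default=np.float32, repr=False)

    def __post_init__(self):
        if self.architecture not in ("unet", "segnet"):
            raise ConfigurationError(f"unknown architecture {self.architecture!r}")
        if self.depth < 1 or self.base_channels < 1:
            raise ConfigurationError("depth and base_channels must be >= 1")
        if self.input_size % (1 << self.depth) != 0:
            raise ConfigurationError(
                f"input_size {self.input_size} is not divisible by 2^{self.depth}")

    @property
    def bottleneck_size(self) -> int:
        return self.input_size >> self.depth

    @property
    def encoder_channels(self) -> list[int]:
        return [self.base_channels << i for i in range(self.depth)]


class SegModel:
    """Common forward/backward machinery; subclasses wire the decoder."""

    architecture: str

    def __init__(self, config: SegModelConfig):
        self.config = config
        self.bottleneck_shape: tuple[int, int] | None = None
        self._build(np.random.default_rng(config.seed))

    # -- structure -------------------------------------------------------
    def _build(self, rng):  # pragma: no cover - interface
        raise NotImplementedError

    def parameters(self) -> list[nn.Param]:
        return [p for lay in self._all_layers() for p in lay.params()]

    def count_params(self) -> int:
        return int(sum(p.value.size for p in self.parameters()))

    def summary(self) -> list[dict]:
        """One row per parametrised layer: name, shapes, parameter count."""
        rows = []
        for name, lay in self._named_layers():
            n = sum(p.value.size for p in lay.params())
            if n:
                rows.append({"layer": name, "type": type(lay).__name__,
                             "params": int(n)})
        return rows

    # -- compute ---------------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def predict_proba(self, x: np.ndarray, batch_size: int = 8) -> np.ndarray:
        """Forward pass in inference mode, batched over axis 0."""
        outs = [self.forward(x[i:i + batch_size])
                for i in range(0, x.shape[0], batch_size)]
        return np.concatenate(outs, axis=0)


class UNet(SegModel):
    architecture = "unet"

    def _build(self, rng):
        cfg = self.config
        ch = cfg.encoder_channels
        dt = cfg.dtype
        self.enc_blocks, self.pools = [], []
        prev = 1
        for c in ch:
            self.enc_blocks.append(nn.ConvBlock(prev, c, rng, dtype=dt))
            self.pools.append(nn.MaxPool2d())
            prev = c
        self.upconvs, self.dec_blocks = [], []
        for c in reversed(ch):
            self.upconvs.append(nn.ConvTranspose2d(prev, c, rng, dtype=dt))
            self.dec_blocks.append(nn.ConvBlock(2 * c, c, rng, dtype=dt))
            prev = c
        self.head = nn.Conv2d(prev, 1, 1, rng, dtype=dt, init_scale=0.0)
        self.out_act = nn.Sigmoid()

    def _all_layers(self):
        return (self.enc_blocks + self.pools + self.upconvs + self.dec_blocks
                + [self.head, self.out_act])

    def _named_layers(self):
        for i, b in enumerate(self.enc_blocks):
            yield f"enc{i + 1}", b
        for i, (u, b) in enumerate(zip(self.upconvs, self.dec_blocks)):
            yield f"up{len(self.upconvs) - i}", u
            yield f"dec{len(self.dec_blocks) - i}", b
        yield "head", self.head

    def forward(self, x):
        skips = []
        for block, pool in zip(self.enc_blocks, self.pools):
            x = block.forward(x)
            skips.append(x)
            x = pool.forward(x)
        self.bottleneck_shape = x.shape[1:3]
        self._skip_channels = [s.shape[3] for s in skips]
        for up, block, skip in zip(self.upconvs, self.dec_blocks, reversed(skips)):
            x = up.forward(x)
            x = block.forward(np.concatenate([skip, x], axis=3))
        return self.out_act.forward(self.head.forward(x))

    def backward(self, gy):
        gy = self.head.backward(self.out_act.backward(gy))
        gskips = []
        for up, block in zip(reversed(self.upconvs), reversed(self.dec_blocks)):
            g = block.backward(gy)
            c = up.w.value.shape[1]  # upsampled half of the concat
            gskips.append(g[..., :-c])
            gy = up.backward(g[..., -c:])
        gskips.reverse()  # gskips[i] pairs with encoder stage depth-1-i
        for block, pool, gskip in zip(reversed(self.enc_blocks),
                                      reversed(self.pools), gskips):
            gy = block.backward(pool.backward(gy) + gskip)
        return gy


class SegNet(SegModel):
    architecture = "segnet"

    def _build(self, rng):
        cfg = self.config
        ch = cfg.encoder_channels
        dt = cfg.dtype
        self.enc_blocks, self.pools = [], []
        prev = 1
        for c in ch:
            self.enc_blocks.append(nn.ConvBlock(prev, c, rng, dtype=dt))
            self.pools.append(nn.MaxPool2d())
            prev = c
        # Unpooling must see the channel count its recorded indices came
        # from, so each decoder conv block reduces to the next stage's
        # width before that stage's unpool runs.
        self.unpools, self.dec_blocks = [], []
        for i in reversed(range(len(ch))):
            self.unpools.append(nn.MaxUnpool2d(self.pools[i]))
            out_c = ch[i - 1] if i > 0 else ch[0]
            self.dec_blocks.append(nn.ConvBlock(ch[i], out_c, rng, dtype=dt))
            prev = out_c
        self.head = nn.Conv2d(prev, 1, 1, rng, dtype=dt, init_scale=0.0)
        self.out_act = nn.Sigmoid()

    def _all_layers(self):
        return (self.enc_blocks + self.pools + self.unpools + self.dec_blocks
                + [self.head, self.out_act])

    def _named_layers(self):
        for i, b in enumerate(self.enc_blocks):
            yield f"enc{i + 1}", b
        for i, b in enumerate(self.dec_blocks):
            yield f"dec{len(self.dec_blocks) - i}", b
        yield "head", self.head

    def forward(self, x):
        for block, pool in zip(self.enc_blocks, self.pools):
            x = pool.forward(block.forward(x))
        self.bottleneck_shape = x.shape[1:3]
        for unpool, block in zip(self.unpools, self.dec_blocks):
            x = block.forward(unpool.forward(x))
        return self.out_act.forward(self.head.forward(x))

    def backward(self, gy):
        gy = self.head.backward(self.out_act.backward(gy))
        for unpool, block in zip(reversed(self.unpools), reversed(self.dec_blocks)):
            gy = unpool.backward(block.backward(gy))
        for block, pool in zip(reversed(self.enc_blocks), reversed(self.pools)):
            gy = block.backward(pool.backward(gy))
        return gy


def build_unet(config: SegModelConfig | None = None, **kwargs) -> UNet:
    config = config or SegModelConfig(architecture="unet", **kwargs)
    return UNet(config)


def build_segnet(config: SegModelConfig | None = None, **kwargs) -> SegNet:
    if config is None:
        kwargs.setdefault("architecture", "segnet")
        config = SegModelConfig(**kwargs)
    return SegNet(config)


def build_model(config: SegModelConfig) -> SegModel:
    return UNet(config) if config.architecture == "unet" else SegNet(config)


def predict_mask(model: SegModel, frame, threshold: float = 0.5) -> np.ndarray:
    """Binarize the model's per-pixel probability at ``threshold``.

    ``frame`` may be an 8-bit image array (rescaled to [0, 1]), a float array
    already in [0, 1], or an :class:`~nervetrace.phantoms.UltrasoundFrame`.
    """
    pix = np.asarray(getattr(frame, "pixels", frame))
    if pix.shape != (model.config.input_size, model.config.input_size):
        raise GeometryError(
            f"frame shape {pix.shape} does not match model input size "
            f"{model.config.input_size}")
    x = pix.astype(model.config.dtype)
    if pix.dtype.kind in "ui" or x.max() > 1.0:
        x = x / 255.0
    prob = model.forward(x[None, :, :, None])[0, :, :, 0]
    return (prob >= threshold).astype(np.uint8)


def save_checkpoint(model: SegModel, path) -> None:
    """Serialize architecture config + weights into one ``.npz`` file."""
    cfg = model.config
    meta = json.dumps({"architecture": cfg.architecture,
                       "input_size": cfg.input_size, "depth": cfg.depth,
                       "base_channels": cfg.base_channels, "seed": cfg.seed})
    arrays = {f"p{i}": p.value for i, p in enumerate(model.parameters())}
    np.savez(path, _meta=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> SegModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["_meta"]).decode())
        model = build_model(SegModelConfig(**meta))
        for i, p in enumerate(model.parameters()):
            p.value[...] = data[f"p{i}"]
    return model
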