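"""A compact UNet over the explicit-backprop layers.

Encoder/decoder with two 3×3 conv + batch-norm + ReLU blocks per level,
2×2 max pooling down, nearest-neighbour upsampling and skip concatenation
up, and a 1×1 sigmoid head.  Inputs of any spatial size ≥ 8 are zero-padded
to a multiple of the downsampling factor and the output is cropped back, so
output H, W always equal input H, W.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .layers import BatchNorm2d, Conv2d, Layer, MaxPool2d, ReLU, Sigmoid, Upsample2x


class ConfigError(ValueError):
    """Raised for inconsistent architecture or training configuration."""


@dataclass(frozen=True)
class BackboneSpec:
    """UNet architecture description.

    ``channels_per_level`` widths from finest to coarsest level; the default
    follows the cellpose-style backbone (32, 64, 128, 256).
    """

    channels_per_level: tuple[int, ...] = (32, 64, 128, 256)
    in_channels: int = 1
    out_channels: int = 1
    nonlinearity: str = "relu"
    normalization: str = "batch"

    def __post_init__(self) -> None:
        if len(self.channels_per_level) < 2:
            raise ConfigError("UNet needs at least two levels")
        if self.in_channels < 1 or self.out_channels < 1:
            raise ConfigError("channel counts must be positive")
        if self.nonlinearity != "relu" or self.normalization != "batch":
            raise ConfigError("only relu nonlinearity and batch normalization are built")


class _ConvBlock:
    def __init__(self, in_ch, out_ch, rng, dtype):
        self.layers: list[Layer] = [
            Conv2d(in_ch, out_ch, 3, rng, dtype),
            BatchNorm2d(out_ch, dtype=dtype),
            ReLU(),
            Conv2d(out_ch, out_ch, 3, rng, dtype),
            BatchNorm2d(out_ch, dtype=dtype),
            ReLU(),
        ]

    def forward(self, x, training):
        for l in self.layers:
            x = l.forward(x, training)
        return x

    def backward(self, dout):
        for l in reversed(self.layers):
            dout = l.backward(dout)
        return dout


class UNet:
    """Probability-field predictor: NCHW in, sigmoid NCHW out."""

    def __init__(self, spec: BackboneSpec, seed: int = 0, dtype=np.float32):
        self.spec = spec
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        ch = list(spec.channels_per_level)
        self.depth = len(ch)
        self.factor = 2 ** (self.depth - 1)

        self.enc = [_ConvBlock(spec.in_channels, ch[0], rng, dtype)]
        for l in range(1, self.depth):
            self.enc.append(_ConvBlock(ch[l - 1], ch[l], rng, dtype))
        self.pools = [MaxPool2d() for _ in range(self.depth - 1)]
        self.ups = [Upsample2x() for _ in range(self.depth - 1)]
        self.dec = [
            _ConvBlock(ch[l + 1] + ch[l], ch[l], rng, dtype)
            for l in range(self.depth - 1)
        ]
        self.head = Conv2d(ch[0], spec.out_channels, 1, rng, dtype)
        self.out_act = Sigmoid()
        self._fwd_cache = None

    # -- parameter plumbing ------------------------------------------------
    def _named_layers(self):
        for l, blk in enumerate(self.enc):
            for i, lay in enumerate(blk.layers):
                yield f"enc{l}.{i}", lay
        for l, blk in enumerate(self.dec):
            for i, lay in enumerate(blk.layers):
                yield f"dec{l}.{i}", lay
        yield "head", self.head

    def parameters(self):
        """Stable-ordered list of (layer, param_name) references."""
        out = []
        for _, lay in self._named_layers():
            for k in lay.params:
                out.append((lay, k))
        return out

    def zero_grad(self):
        for _, lay in self._named_layers():
            lay.zero_grad()

    def grad_norm(self) -> float:
        total = 0.0
        for lay, k in self.parameters():
            total += float((lay.grads[k].astype(np.float64) ** 2).sum())
        return float(np.sqrt(total))

    # -- forward / backward ------------------------------------------------
    def _pad(self, x):
        n, c, h, w = x.shape
        f = self.factor
        ph = (-h) % f
        pw = (-w) % f
        if ph or pw:
            x = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)))
        return x, (h, w)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim != 4:
            raise ConfigError(f"expected NCHW input, got shape {x.shape}")
        if x.shape[1] != self.spec.in_channels:
            raise ConfigError(
                f"model expects {self.spec.in_channels} input channels, got {x.shape[1]}"
            )
        x, (h, w) = self._pad(x)
        skips = []
        for l in range(self.depth - 1):
            x = self.enc[l].forward(x, training)
            skips.append(x)
            x = self.pools[l].forward(x, training)
        x = self.enc[-1].forward(x, training)
        split_ch = []
        for l in reversed(range(self.depth - 1)):
            x = self.ups[l].forward(x, training)
            split_ch.append(x.shape[1])
            x = np.concatenate([x, skips[l]], axis=1)
            x = self.dec[l].forward(x, training)
        x = self.head.forward(x, training)
        x = self.out_act.forward(x, training)
        if training:
            self._fwd_cache = (h, w, x.shape, split_ch)
        return x[:, :, :h, :w]

    def backward(self, dout: np.ndarray) -> None:
        """Accumulate parameter gradients from d(loss)/d(output)."""
        if self._fwd_cache is None:
            raise RuntimeError("backward() requires a preceding training forward()")
        h, w, padded_shape, split_ch = self._fwd_cache
        self._fwd_cache = None
        full = np.zeros(padded_shape, dtype=self.dtype)
        full[:, :, :h, :w] = dout
        d = self.out_act.backward(full)
        d = self.head.backward(d)
        dskips = [None] * (self.depth - 1)
        for idx, l in enumerate(range(self.depth - 1)):
            d = self.dec[l].backward(d)
            nch = split_ch[len(split_ch) - 1 - l]
            d, dskip = d[:, :nch], d[:, nch:]
            dskips[l] = dskip
            d = self.ups[l].backward(d)
        d = self.enc[-1].backward(d)
        for l in reversed(range(self.depth - 1)):
            d = self.pools[l].backward(d)
            d = d + dskips[l]
            d = self.enc[l].backward(d)

    # -- persistence ---------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        st = {}
        for name, lay in self._named_layers():
            for k, v in lay.params.items():
                st[f"{name}.{k}"] = v
            if isinstance(lay, BatchNorm2d):
                st[f"{name}.running_mean"] = lay.running_mean
                st[f"{name}.running_var"] = lay.running_var
        return st

    def load_state_dict(self, st: dict[str, np.ndarray]) -> None:
        for name, lay in self._named_layers():
            for k in lay.params:
                lay.params[k] = np.asarray(st[f"{name}.{k}"], dtype=self.dtype)
            if isinstance(lay, BatchNorm2d):
                lay.running_mean = np.asarray(st[f"{name}.running_mean"], dtype=self.dtype)
                lay.running_var = np.asarray(st[f"{name}.running_var"], dtype=self.dtype)
            lay.zero_grad()

    def save(self, path: str | Path) -> None:
        """Checkpoint: one ``.npz`` with all weights plus the spec as JSON."""
        path = Path(path)
        meta = json.dumps(asdict(self.spec))
        np.savez(path, __spec__=np.array(meta), **self.state_dict())

    @classmethod
    def load(cls, path: str | Path) -> "UNet":
        with np.load(Path(path), allow_pickle=False) as z:
            meta = json.loads(str(z["__spec__"]))
            meta["channels_per_level"] = tuple(meta["channels_per_level"])
            model = cls(BackboneSpec(**meta))
            model.load_state_dict({k: z[k] for k in z.files if k != "__spec__"})
        return model
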