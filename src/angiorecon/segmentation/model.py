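"""The 3D segmentation-and-recognition network.

Architecture: an input unit (a 3D convolution merging the two input
sequences), four down-sampling units built from bottleneck residual
blocks, four up-sampling units whose residual blocks merge the
same-scale encoder outputs through skip connections, instance
normalisation inside every block, and a 1x1x1 convolution head that
emits per-voxel class scores. The black-blood model takes two channels
(T1WI / T1WI-CE); the bright-blood model takes a single TOF channel.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .nn import Adam, Conv3d, ConvTranspose3d, InstanceNorm3d, Param, ReLU

__all__ = ["NetConfig", "Model", "build_model", "save_model", "load_model"]


@dataclass
class NetConfig:
    """Hyperparameters of the segmentation network."""

    in_channels: int = 2          # 2 = dual black-blood, 1 = bright-blood
    n_classes: int = 9            # background + 8 artery classes
    base_width: int = 8
    n_scales: int = 4
    norm: bool = True
    width_cap_factor: int = 8     # channel growth saturates at cap*base
    seed: int = 0

    def __post_init__(self) -> None:
        if self.in_channels not in (1, 2):
            raise ValueError("in_channels must be 1 or 2")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.n_scales < 1:
            raise ValueError("n_scales must be >= 1")

    @property
    def widths(self) -> list[int]:
        cap = self.width_cap_factor * self.base_width
        return [min(self.base_width * 2 ** s, cap)
                for s in range(self.n_scales + 1)]

    @property
    def divisor(self) -> int:
        return 2 ** self.n_scales


class _Seq:
    """A plain forward/backward chain of layers."""

    def __init__(self, *layers):
        self.layers = list(layers)

    @property
    def params(self):
        return [p for l in self.layers for p in l.params]

    def forward(self, x):
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


class BottResidual:
    """Bottleneck residual block: 1x1x1 reduce -> 3x3x3 -> 1x1x1 expand + skip.

    Preserves the input through the identity path; instance norm after
    each convolution.
    """

    def __init__(self, c: int, rng, norm: bool = True):
        mid = max(c // 2, 1)
        def maybe_norm(ch):
            return [InstanceNorm3d(ch)] if norm else []
        self.path = _Seq(
            Conv3d(c, mid, k=1, rng=rng), *maybe_norm(mid), ReLU(),
            Conv3d(mid, mid, k=3, rng=rng), *maybe_norm(mid), ReLU(),
            Conv3d(mid, c, k=1, rng=rng), *maybe_norm(c),
        )
        self.out_relu = ReLU()

    @property
    def params(self):
        return self.path.params

    def forward(self, x):
        self._x_needed = True
        y = self.path.forward(x) + x
        return self.out_relu.forward(y)

    def backward(self, dy):
        dy = self.out_relu.backward(dy)
        dx_path = self.path.backward(dy)
        return dx_path + dy          # identity branch


class _Down:
    """Strided-convolution down-sampling unit + bottleneck residual block."""

    def __init__(self, c_in: int, c_out: int, rng, norm: bool):
        layers = [Conv3d(c_in, c_out, k=3, stride=2, rng=rng)]
        if norm:
            layers.append(InstanceNorm3d(c_out))
        layers.append(ReLU())
        self.seq = _Seq(*layers, BottResidual(c_out, rng, norm))

    @property
    def params(self):
        return self.seq.params

    forward = lambda self, x: self.seq.forward(x)
    backward = lambda self, dy: self.seq.backward(dy)


class _Up:
    """Transposed-conv up-sampling + same-scale skip merge + residual block."""

    def __init__(self, c_deep: int, c_skip: int, rng, norm: bool):
        self.up = ConvTranspose3d(c_deep, c_skip, k=2, rng=rng)
        merge = [Conv3d(2 * c_skip, c_skip, k=1, rng=rng)]
        if norm:
            merge.append(InstanceNorm3d(c_skip))
        merge.append(ReLU())
        self.merge = _Seq(*merge, BottResidual(c_skip, rng, norm))
        self.c_skip = c_skip

    @property
    def params(self):
        return self.up.params + self.merge.params

    def forward(self, deep, skip):
        u = self.up.forward(deep)
        return self.merge.forward(np.concatenate([skip, u], axis=0))

    def backward(self, dy):
        d = self.merge.backward(dy)
        d_skip, d_up = d[:self.c_skip], d[self.c_skip:]
        return self.up.backward(np.ascontiguousarray(d_up)), d_skip


class Model:
    """Encoder-decoder segmentation network (single-sample, numpy)."""

    def __init__(self, config: NetConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        w = config.widths
        stem = [Conv3d(config.in_channels, w[0], k=3, rng=rng)]
        if config.norm:
            stem.append(InstanceNorm3d(w[0]))
        stem.append(ReLU())
        self.stem = _Seq(*stem)
        self.downs = [_Down(w[s], w[s + 1], rng, config.norm)
                      for s in range(config.n_scales)]
        self.ups = [_Up(w[s + 1], w[s], rng, config.norm)
                    for s in reversed(range(config.n_scales))]
        self.head = Conv3d(w[0], config.n_classes, k=1, rng=rng)

    @property
    def params(self) -> list[Param]:
        out = list(self.stem.params)
        for d in self.downs:
            out += d.params
        for u in self.ups:
            out += u.params
        out += self.head.params
        return out

    def forward(self, x: np.ndarray) -> np.ndarray:
        """(in_channels, D, H, W) -> (n_classes, D, H, W) logits.

        Spatial dims must be divisible by ``2**n_scales`` (callers pad).
        """
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 4 or x.shape[0] != self.config.in_channels:
            raise ValueError(
                f"expected ({self.config.in_channels}, D, H, W), got {x.shape}")
        div = self.config.divisor
        if any(s % div for s in x.shape[1:]):
            raise ValueError(
                f"spatial dims {x.shape[1:]} not divisible by {div}; "
                "pad the input explicitly (see segment())")
        skips = [self.stem.forward(x)]
        for d in self.downs:
            skips.append(d.forward(skips[-1]))
        deep = skips.pop()
        self._n_skips = len(skips)
        for u in self.ups:
            deep = u.forward(deep, skips.pop())
        return self.head.forward(deep)

    def backward(self, dlogits: np.ndarray) -> None:
        """Accumulate parameter gradients for the cached forward pass."""
        d = self.head.backward(dlogits)
        # decoder ran deepest-first; unwind it shallow-first, collecting the
        # gradient flowing into each encoder skip
        skip_grads = []                       # index s -> gradient wrt skip s
        for u in reversed(self.ups):          # shallow-first: scale 0, 1, ...
            d, d_skip = u.backward(d)
            skip_grads.append(d_skip)
        # d is now the gradient wrt the deepest encoder output
        for s, down in reversed(list(enumerate(self.downs))):
            d = down.backward(d) + skip_grads[s]
        self.stem.backward(d)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def get_state(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params]

    def set_state(self, state: list[np.ndarray]) -> None:
        for p, v in zip(self.params, state, strict=True):
            p.value[...] = v


def build_model(config: NetConfig) -> Model:
    """Construct the network for a given configuration."""
    return Model(config)


def save_model(model: Model, path) -> None:
    """Checkpoint: NetConfig (json) + flat parameter list (npz)."""
    arrays = {f"p{i}": p.value for i, p in enumerate(model.params)}
    np.savez(path, __config__=np.frombuffer(
        json.dumps(asdict(model.config)).encode(), dtype=np.uint8), **arrays)


def load_model(path) -> Model:
    with np.load(path) as data:
        cfg = NetConfig(**json.loads(bytes(data["__config__"]).decode()))
        model = Model(cfg)
        state = [data[f"p{i}"] for i in range(len(model.params))]
    model.set_state(state)
    return model
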