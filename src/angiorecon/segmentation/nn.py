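"""Minimal 3D convolutional network primitives in numpy.

Each layer implements an explicit ``forward``/``backward`` pair on
single-sample tensors of shape ``(C, D, H, W)`` (float32). Convolutions
run through im2col + BLAS matmul; the input gradient is computed as the
transposed convolution through the same machinery. All backward passes
are validated against finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Param", "Conv3d", "ConvTranspose3d", "InstanceNorm3d", "ReLU",
           "softmax", "softmax_backward", "Adam"]


class Param:
    """A learnable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def _pad_spatial(x: np.ndarray, pad: int, extra: tuple[int, int, int] = (0, 0, 0)
                 ) -> np.ndarray:
    if pad == 0 and not any(extra):
        return x
    return np.pad(x, ((0, 0), (pad, pad + extra[0]), (pad, pad + extra[1]),
                      (pad, pad + extra[2])))


def _im2col(x: np.ndarray, k: int, stride: int) -> tuple[np.ndarray, tuple]:
    """(C, D, H, W) -> (N_out_voxels, C*k^3) columns + output spatial shape."""
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k, k), axis=(1, 2, 3))
    win = win[:, ::stride, ::stride, ::stride]
    _, d, h, w = win.shape[:4]
    cols = win.transpose(1, 2, 3, 0, 4, 5, 6).reshape(d * h * w, -1)
    return np.ascontiguousarray(cols), (d, h, w)


class Conv3d:
    """3D convolution, odd kernel, 'same'-style padding, optional stride."""

    def __init__(self, c_in: int, c_out: int, k: int = 3, stride: int = 1,
                 rng: np.random.Generator | None = None):
        if k % 2 == 0:
            raise ValueError("Conv3d expects an odd kernel size")
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * k ** 3
        scale = np.sqrt(2.0 / fan_in)                       # He init
        self.weight = Param(rng.normal(0.0, scale, (c_out, fan_in)))
        self.bias = Param(np.zeros(c_out))
        self.c_in, self.c_out, self.k, self.stride = c_in, c_out, k, stride
        self.pad = (k - 1) // 2
        self._cols: np.ndarray | None = None
        self._in_shape: tuple | None = None

    @property
    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        xp = _pad_spatial(x, self.pad)
        cols, out_sp = self._fwd_cols(xp)
        self._cols = cols
        y = cols @ self.weight.value.T + self.bias.value
        return np.ascontiguousarray(y.T.reshape(self.c_out, *out_sp))

    def _fwd_cols(self, xp):
        return _im2col(xp, self.k, self.stride)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        c_out = self.c_out
        dy_flat = dy.reshape(c_out, -1).T                     # (N, c_out)
        self.weight.grad += dy_flat.T @ self._cols
        self.bias.grad += dy_flat.sum(axis=0)
        self._cols = None

        # input gradient = transposed convolution of dy
        k, s, p = self.k, self.stride, self.pad
        _, D, H, W = self._in_shape
        dsp = dy.shape[1:]
        if s > 1:           # zero-stuff between output samples
            dz = np.zeros((c_out, s * (dsp[0] - 1) + 1, s * (dsp[1] - 1) + 1,
                           s * (dsp[2] - 1) + 1), dtype=dy.dtype)
            dz[:, ::s, ::s, ::s] = dy
        else:
            dz = dy
        target = (D + 2 * p, H + 2 * p, W + 2 * p)
        base = tuple(dz.shape[1 + a] + 2 * (k - 1) - k + 1 for a in range(3))
        extra = tuple(t - b for t, b in zip(target, base))
        dzp = _pad_spatial(dz, k - 1, extra)
        cols, _ = _im2col(dzp, k, 1)
        # W viewed as (c_out, c_in, k^3); flipped kernel, in/out swapped
        wf = self.weight.value.reshape(c_out, self.c_in, -1)[:, :, ::-1]
        wmat = wf.transpose(1, 0, 2).reshape(self.c_in, -1)   # (c_in, c_out*k^3)
        dxp = (cols @ wmat.T).T.reshape(self.c_in, *target)
        if p:
            dxp = dxp[:, p:p + D, p:p + H, p:p + W]
        return np.ascontiguousarray(dxp)


class ConvTranspose3d:
    """Transposed 3D convolution with kernel == stride (block upsampling)."""

    def __init__(self, c_in: int, c_out: int, k: int = 2,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * k ** 3
        scale = np.sqrt(2.0 / fan_in)
        self.weight = Param(rng.normal(0.0, scale, (c_in, c_out, k, k, k)))
        self.bias = Param(np.zeros(c_out))
        self.c_in, self.c_out, self.k = c_in, c_out, k
        self._x: np.ndarray | None = None

    @property
    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        k = self.k
        _, D, H, W = x.shape
        t = np.tensordot(self.weight.value, x, axes=([0], [0]))
        # (c_out, k, k, k, D, H, W) -> (c_out, D, k, H, k, W, k)
        t = t.transpose(0, 4, 1, 5, 2, 6, 3)
        y = t.reshape(self.c_out, D * k, H * k, W * k)
        return np.ascontiguousarray(y + self.bias.value[:, None, None, None])

    def _blocks(self, dy: np.ndarray) -> np.ndarray:
        k = self.k
        c, Dk, Hk, Wk = dy.shape
        b = dy.reshape(c, Dk // k, k, Hk // k, k, Wk // k, k)
        return b.transpose(0, 2, 4, 6, 1, 3, 5)    # (c_out, k,k,k, D,H,W)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b = self._blocks(dy)
        self.bias.grad += dy.sum(axis=(1, 2, 3))
        self.weight.grad += np.tensordot(self._x, b, axes=([1, 2, 3], [4, 5, 6]))
        dx = np.tensordot(self.weight.value, b, axes=([1, 2, 3, 4], [0, 1, 2, 3]))
        self._x = None
        return np.ascontiguousarray(dx.astype(np.float32))


class InstanceNorm3d:
    """Per-channel spatial normalisation with learnable scale/shift."""

    def __init__(self, c: int, eps: float = 1e-5):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.eps = eps
        self._cache = None

    @property
    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=(1, 2, 3), keepdims=True)
        var = x.var(axis=(1, 2, 3), keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv)
        return (self.gamma.value[:, None, None, None] * xhat
                + self.beta.value[:, None, None, None]).astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        self._cache = None
        n = xhat[0].size
        self.gamma.grad += (dy * xhat).sum(axis=(1, 2, 3))
        self.beta.grad += dy.sum(axis=(1, 2, 3))
        dxhat = dy * self.gamma.value[:, None, None, None]
        dx = (inv / n) * (n * dxhat
                          - dxhat.sum(axis=(1, 2, 3), keepdims=True)
                          - xhat * (dxhat * xhat).sum(axis=(1, 2, 3),
                                                      keepdims=True))
        return dx.astype(np.float32)


class ReLU:
    def __init__(self):
        self._mask = None

    @property
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        m = self._mask
        self._mask = None
        return np.where(m, dy, 0.0).astype(np.float32)


def softmax(z: np.ndarray, axis: int = 0) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_backward(p: np.ndarray, dp: np.ndarray, axis: int = 0) -> np.ndarray:
    dot = (p * dp).sum(axis=axis, keepdims=True)
    return (p * (dp - dot)).astype(np.float32)


class Adam:
    """Adam with L2 weight decay folded into the gradient (torch-style)."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999,
                 weight_decay: float = 1e-5, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2 = beta1, beta2
        self.weight_decay = weight_decay
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            g = p.grad + self.weight_decay * p.value
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.value -= lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
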