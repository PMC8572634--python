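"""Minimal CPU neural-network layers with analytic gradients.

All layers operate on NCHW float32 arrays and implement ``forward(x, train)``
and ``backward(dout)``; parameters and their gradients live in ``params`` /
``grads`` dicts keyed by name. Gradients are exact (verified against finite
differences in the test suite), which keeps the whole model dependency-free
and auditable.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def n_params(self) -> int:
        return sum(p.size for p in self.params.values())


class Conv2d(Layer):
    """Same-padded 2D convolution with optional dilation, via im2col."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3,
                 dilation: int = 1, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.in_ch, self.out_ch, self.k, self.d = in_ch, out_ch, kernel, dilation
        fan_in = in_ch * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)  # He init for ReLU networks
        self.params["W"] = (rng.standard_normal((out_ch, fan_in)) * scale).astype(np.float32)
        self.params["b"] = np.zeros(out_ch, dtype=np.float32)

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        k, d = self.k, self.d
        pad = d * (k - 1) // 2
        self._pad = pad
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        self._xp_shape = xp.shape
        ke = d * (k - 1) + 1
        win = sliding_window_view(xp, (ke, ke), axis=(2, 3))[..., ::d, ::d]
        n, c, h, w = x.shape
        # (N, C, H, W, k, k) -> (N*H*W, C*k*k)
        return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * h * w, c * k * k)

    def forward(self, x, train=True):
        self._x_shape = x.shape
        n, c, h, w = x.shape
        cols = self._im2col(x)
        self._cols = cols
        out = cols @ self.params["W"].T + self.params["b"]
        return out.reshape(n, h, w, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, dout):
        n, f, h, w = dout.shape
        k, d = self.k, self.d
        dflat = dout.transpose(0, 2, 3, 1).reshape(n * h * w, f)
        self.grads["W"] = (dflat.T @ self._cols).astype(np.float32)
        self.grads["b"] = dflat.sum(axis=0).astype(np.float32)
        dcols = dflat @ self.params["W"]  # (N*H*W, C*k*k)
        c = self.in_ch
        dcols = dcols.reshape(n, h, w, c, k, k).transpose(0, 3, 1, 2, 4, 5)
        dxp = np.zeros(self._xp_shape, dtype=np.float32)
        for ki in range(k):
            for kj in range(k):
                dxp[:, :, ki * d:ki * d + h, kj * d:kj * d + w] += dcols[:, :, :, :, ki, kj]
        p = self._pad
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics for inference."""

    def __init__(self, ch: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.params["gamma"] = np.ones(ch, dtype=np.float32)
        self.params["beta"] = np.zeros(ch, dtype=np.float32)
        self.running_mean = np.zeros(ch, dtype=np.float32)
        self.running_var = np.ones(ch, dtype=np.float32)

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean).astype(np.float32)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        m = mean[None, :, None, None]
        v = var[None, :, None, None]
        self._std = np.sqrt(v + self.eps)
        self._xhat = (x - m) / self._std
        self._train = train
        return self.params["gamma"][None, :, None, None] * self._xhat \
            + self.params["beta"][None, :, None, None]

    def backward(self, dout):
        g = self.params["gamma"][None, :, None, None]
        self.grads["gamma"] = (dout * self._xhat).sum(axis=(0, 2, 3)).astype(np.float32)
        self.grads["beta"] = dout.sum(axis=(0, 2, 3)).astype(np.float32)
        dxhat = dout * g
        if not self._train:
            return dxhat / self._std
        n = dout.shape[0] * dout.shape[2] * dout.shape[3]
        # standard batch-norm backward: couples dx through batch mean/variance
        dx = (dxhat - dxhat.mean(axis=(0, 2, 3), keepdims=True)
              - self._xhat * (dxhat * self._xhat).mean(axis=(0, 2, 3), keepdims=True))
        return dx / self._std


class ReLU(Layer):
    def forward(self, x, train=True):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout):
        return np.where(self._mask, dout, 0.0)


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; requires even spatial dims."""

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"MaxPool2 requires even spatial dims, got {h}x{w}")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // 2, w // 2, 4)
        self._arg = xr.argmax(axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(xr, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        n, c, h, w = self._in_shape
        dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=np.float32)
        np.put_along_axis(dxr, self._arg[..., None], dout[..., None], axis=-1)
        return dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(
            0, 1, 2, 4, 3, 5).reshape(n, c, h, w)


class UpsampleBilinear2(Layer):
    """Factor-2 bilinear upsampling (half-pixel-center convention); the
    backward pass is the exact transpose of the interpolation weights."""

    def _weights(self, n_in: int):
        src = (np.arange(2 * n_in) + 0.5) / 2.0 - 0.5
        i0 = np.clip(np.floor(src).astype(int), 0, n_in - 1)
        i1 = np.clip(i0 + 1, 0, n_in - 1)
        w1 = np.clip(src - i0, 0.0, 1.0)
        return i0, i1, (1.0 - w1).astype(np.float32), w1.astype(np.float32)

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        self._in_shape = x.shape
        self._wy = self._weights(h)
        self._wx = self._weights(w)
        i0, i1, a0, a1 = self._wy
        y = x[:, :, i0, :] * a0[None, None, :, None] + x[:, :, i1, :] * a1[None, None, :, None]
        j0, j1, b0, b1 = self._wx
        return y[:, :, :, j0] * b0[None, None, None, :] + y[:, :, :, j1] * b1[None, None, None, :]

    def backward(self, dout):
        n, c, h, w = self._in_shape
        j0, j1, b0, b1 = self._wx
        dy = np.zeros((n, c, 2 * h, w), dtype=np.float32)
        np.add.at(dy, (slice(None), slice(None), slice(None), j0),
                  dout * b0[None, None, None, :])
        np.add.at(dy, (slice(None), slice(None), slice(None), j1),
                  dout * b1[None, None, None, :])
        i0, i1, a0, a1 = self._wy
        dx = np.zeros((n, c, h, w), dtype=np.float32)
        np.add.at(dx, (slice(None), slice(None), i0), dy * a0[None, None, :, None])
        np.add.at(dx, (slice(None), slice(None), i1), dy * a1[None, None, :, None])
        return dx


class Sigmoid(Layer):
    def forward(self, x, train=True):
        out = np.empty_like(x)
        np.negative(np.abs(x), out=out)
        np.exp(out, out=out)
        self._y = np.where(x >= 0, 1.0 / (1.0 + out), out / (1.0 + out))
        return self._y

    def backward(self, dout):
        return dout * self._y * (1.0 - self._y)


class GlobalPoolBranch(Layer):
    """ASPP image-level branch: global average pool -> 1x1 conv -> ReLU ->
    broadcast back to the feature map's spatial size."""

    def __init__(self, in_ch: int, out_ch: int, rng=None):
        super().__init__()
        self.conv = Conv2d(in_ch, out_ch, kernel=1, rng=rng)
        self.relu = ReLU()
        self.params = self.conv.params
        self.grads = self.conv.grads

    def forward(self, x, train=True):
        self._hw = x.shape[2:]
        g = x.mean(axis=(2, 3), keepdims=True)
        y = self.relu.forward(self.conv.forward(g, train), train)
        return np.broadcast_to(y, y.shape[:2] + self._hw).copy()

    def backward(self, dout):
        dg = self.conv.backward(self.relu.backward(dout.sum(axis=(2, 3), keepdims=True)))
        h, w = self._hw
        return np.broadcast_to(dg / (h * w), dg.shape[:2] + self._hw).astype(np.float32)


class ConvBlock(Layer):
    """conv(k=3) -> batch norm -> ReLU."""

    def __init__(self, in_ch, out_ch, kernel=3, dilation=1, rng=None, norm=True):
        super().__init__()
        self.conv = Conv2d(in_ch, out_ch, kernel, dilation, rng)
        self.bn = BatchNorm2d(out_ch) if norm else None
        self.relu = ReLU()

    def forward(self, x, train=True):
        y = self.conv.forward(x, train)
        if self.bn is not None:
            y = self.bn.forward(y, train)
        return self.relu.forward(y, train)

    def backward(self, dout):
        d = self.relu.backward(dout)
        if self.bn is not None:
            d = self.bn.backward(d)
        return self.conv.backward(d)

    def sublayers(self):
        return [self.conv] + ([self.bn] if self.bn is not None else [])

    def n_params(self):
        return sum(l.n_params() for l in self.sublayers())
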