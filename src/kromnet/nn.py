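"""Minimal CNN building blocks on numpy with hand-derived backpropagation.

Layers keep the NCHW layout and float32 arithmetic (float64 available for
gradient checking).  Convolution is computed by the shift-and-GEMM scheme:
for a k x k kernel the input is padded once and the output accumulated over
the k^2 kernel taps with one BLAS matrix product per tap, which also gives
dilated convolution for free (tap offsets stride by the dilation rate).

Every layer implements ``forward(x)`` and ``backward(dout)``; ``backward``
must be called with the gradient of the scalar loss w.r.t. the forward
output and returns the gradient w.r.t. the forward input, accumulating
parameter gradients in ``Param.grad``.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv2d",
    "ReLU",
    "MaxPool2d",
    "ChannelAttention",
    "Flatten",
    "Linear",
    "Sequential",
    "softmax",
    "softmax_cross_entropy",
    "Adam",
    "SGD",
]


class Param:
    """A learnable tensor and the gradient accumulated for it."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = value
        self.grad = np.zeros_like(value)
        self.name = name


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, dtype) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


class Conv2d(Layer):
    """2-D convolution (cross-correlation), stride >= 1, dilation >= 1.

    ``padding='same'`` preserves the spatial size at stride 1 for odd
    kernels by padding ``dilation * (kernel - 1) // 2`` zeros per side —
    the effective kernel extent is ``kernel + (kernel - 1)(dilation - 1)``.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int = 3,
        stride: int = 1,
        dilation: int = 1,
        padding: int | str = "same",
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ):
        if dilation < 1:
            raise ValueError(f"dilation rate must be >= 1, got {dilation}")
        if stride < 1:
            raise ValueError(f"stride must be >= 1, got {stride}")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.dilation = dilation
        if padding == "same":
            if kernel_size % 2 == 0:
                raise ValueError("'same' padding requires an odd kernel")
            padding = dilation * (kernel_size - 1) // 2
        self.padding = int(padding)
        rng = rng if rng is not None else np.random.default_rng(0)
        fan_in = in_channels * kernel_size * kernel_size
        self.w = Param(
            _he_init(rng, (out_channels, in_channels, kernel_size, kernel_size), fan_in, dtype),
            "conv.w",
        )
        self.b = Param(np.zeros(out_channels, dtype=dtype), "conv.b")
        self._cache = None

    @property
    def effective_extent(self) -> int:
        return self.kernel_size + (self.kernel_size - 1) * (self.dilation - 1)

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def _out_size(self, n: int) -> int:
        return (n + 2 * self.padding - self.effective_extent) // self.stride + 1

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} channels, got {c}")
        k, s, d, p = self.kernel_size, self.stride, self.dilation, self.padding
        ho, wo = self._out_size(h), self._out_size(w)
        if ho < 1 or wo < 1:
            raise ValueError(f"input {h}x{w} too small for effective kernel {self.effective_extent}")
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        out = np.zeros((n, ho, wo, self.out_channels), dtype=x.dtype)
        wk = self.w.value
        for i in range(k):
            for j in range(k):
                xs = xp[:, :, i * d : i * d + s * (ho - 1) + 1 : s,
                        j * d : j * d + s * (wo - 1) + 1 : s]
                # (N,C,Ho,Wo) x (F,C) -> (N,Ho,Wo,F)
                out += np.tensordot(xs, wk[:, :, i, j], axes=([1], [1]))
        out += self.b.value
        self._cache = (xp, x.shape)
        return np.ascontiguousarray(out.transpose(0, 3, 1, 2))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xp, x_shape = self._cache
        n, c, h, w = x_shape
        k, s, d, p = self.kernel_size, self.stride, self.dilation, self.padding
        ho, wo = dout.shape[2], dout.shape[3]
        g = np.ascontiguousarray(dout.transpose(0, 2, 3, 1))  # (N,Ho,Wo,F)
        self.b.grad += g.sum(axis=(0, 1, 2))
        dxp = np.zeros_like(xp)
        wk = self.w.value
        for i in range(k):
            for j in range(k):
                rs = slice(i * d, i * d + s * (ho - 1) + 1, s)
                cs = slice(j * d, j * d + s * (wo - 1) + 1, s)
                xs = xp[:, :, rs, cs]
                # dW: contract (N,Ho,Wo) between g and xs -> (F, C)
                self.w.grad[:, :, i, j] += np.tensordot(g, xs, axes=([0, 1, 2], [0, 2, 3]))
                # dx: (N,Ho,Wo,F) x (F,C) -> (N,Ho,Wo,C)
                gi = np.tensordot(g, wk[:, :, i, j], axes=([3], [0]))
                dxp[:, :, rs, cs] += gi.transpose(0, 3, 1, 2)
        if p:
            return dxp[:, :, p : p + h, p : p + w]
        return dxp


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool2d(Layer):
    """2x2 max pooling, stride 2; spatial dims must be even.

    Ties route the gradient to the first maximal element in raster order,
    keeping backward fully deterministic.
    """

    def __init__(self, size: int = 2):
        if size != 2:
            raise ValueError("only 2x2 pooling is supported")
        self.size = size

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"spatial dims must be even for 2x2 pooling, got {h}x{w}")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = np.ascontiguousarray(xr).reshape(n, c, h // 2, w // 2, 4)
        self._idx = np.argmax(xr, axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._in_shape
        dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=dout.dtype)
        np.put_along_axis(dxr, self._idx[..., None], dout[..., None], axis=-1)
        dxr = dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return np.ascontiguousarray(dxr).reshape(n, c, h, w)


class ChannelAttention(Layer):
    """Squeeze-style channel attention: GAP -> FC bottleneck -> sigmoid gate.

    The C-vector of per-channel spatial means passes through a reducing
    fully connected map (C -> C/r), ReLU, an expanding map (C/r -> C) and a
    sigmoid; the resulting weights in (0, 1) rescale the feature map channel
    by channel.  Biases are carried on both maps.
    """

    def __init__(
        self,
        channels: int,
        reduction: int = 16,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ):
        if channels % reduction != 0:
            raise ValueError(f"reduction {reduction} must divide channels {channels}")
        self.channels = channels
        self.reduction = reduction
        hidden = channels // reduction
        rng = rng if rng is not None else np.random.default_rng(0)
        self.w1 = Param(_he_init(rng, (hidden, channels), channels, dtype), "att.w1")
        self.b1 = Param(np.zeros(hidden, dtype=dtype), "att.b1")
        self.w2 = Param(_he_init(rng, (channels, hidden), hidden, dtype), "att.w2")
        self.b2 = Param(np.zeros(channels, dtype=dtype), "att.b2")
        self.last_weights: np.ndarray | None = None  # (N, C) gates from last forward
        self.last_pooled: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.w1, self.b1, self.w2, self.b2]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        m2 = x.mean(axis=(2, 3))                          # squeeze (N, C)
        z = m2 @ self.w1.value.T + self.b1.value
        a = np.maximum(z, 0.0)
        s = a @ self.w2.value.T + self.b2.value
        m3 = 1.0 / (1.0 + np.exp(-s))                     # gates in (0, 1)
        self._cache = (x, m2, z, a, m3, h * w)
        self.last_weights = m3
        self.last_pooled = m2
        return x * m3[:, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, m2, z, a, m3, hw = self._cache
        dm3 = (dout * x).sum(axis=(2, 3))
        dx = dout * m3[:, :, None, None]
        ds = dm3 * m3 * (1.0 - m3)
        self.w2.grad += ds.T @ a
        self.b2.grad += ds.sum(axis=0)
        da = ds @ self.w2.value
        dz = da * (z > 0)
        self.w1.grad += dz.T @ m2
        self.b1.grad += dz.sum(axis=0)
        dm2 = dz @ self.w1.value
        dx += (dm2 / hw)[:, :, None, None]
        return dx


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Linear(Layer):
    def __init__(
        self,
        in_features: int,
        out_features: int,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.w = Param(_he_init(rng, (out_features, in_features), in_features, dtype), "fc.w")
        self.b = Param(np.zeros(out_features, dtype=dtype), "fc.b")

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w.value.T + self.b.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.w.grad += dout.T @ self._x
        self.b.grad += dout.sum(axis=0)
        return dout @ self.w.value


class Sequential(Layer):
    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax, stable for logits of any magnitude."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, onehot: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. logits.

    Returns ``(loss, dlogits, probs)``; the fused form keeps the gradient
    ``(probs - onehot) / N`` numerically exact even for saturated rows.
    """
    n = logits.shape[0]
    z = logits - logits.max(axis=-1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=-1, keepdims=True))
    logp = z - logsumexp
    loss = float(-(onehot * logp).sum() / n)
    probs = np.exp(logp)
    dlogits = (probs - onehot) / n
    return loss, dlogits.astype(logits.dtype), probs


class Adam:
    """Adam with the standard bias correction (beta1=0.9, beta2=0.999)."""

    def __init__(self, params: Sequence[Param], lr: float = 2e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


class SGD:
    def __init__(self, params: Sequence[Param], lr: float = 2e-4):
        self.params = list(params)
        self.lr = lr

    def step(self) -> None:
        for p in self.params:
            p.value -= self.lr * p.grad
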