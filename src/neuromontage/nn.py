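"""Minimal CPU neural-network engine.

Implements exactly the pieces the montage classifiers need: 2D convolution
(im2col + GEMM), max pooling, batch normalisation, ReLU, linear layers,
residual blocks, stable binary cross-entropy, and the SGD / RMSProp update
rules.  Forward and backward passes are hand-derived; all state is plain
``numpy`` arrays so models serialise to ``.npz``.

Layers follow a small protocol: ``forward(x)`` caches what backward needs,
``backward(grad)`` returns the gradient w.r.t. the input and accumulates
parameter gradients, ``parameters()`` yields ``Param`` objects.  ``training``
toggles batch-norm behaviour.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Layer",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2d",
    "GlobalAvgPool",
    "Flatten",
    "Linear",
    "Sequential",
    "BasicBlock",
    "SGD",
    "RMSProp",
    "bce_with_logits",
    "sigmoid",
]


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class Param:
    """A trainable array with its gradient accumulator."""

    name: str
    value: np.ndarray
    grad: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.grad is None:
            self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    training: bool = True

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def parameters(self) -> list[Param]:
        return []

    def train(self, mode: bool = True) -> "Layer":
        self.training = mode
        return self

    def eval(self) -> "Layer":
        return self.train(False)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


class Conv2d(Layer):
    """k×k convolution via im2col; stride and zero padding supported."""

    def __init__(self, cin: int, cout: int, k: int, stride: int = 1,
                 pad: int | None = None, bias: bool = True,
                 rng: np.random.Generator | None = None, name: str = "conv"):
        rng = rng or np.random.default_rng(0)
        self.cin, self.cout, self.k, self.stride = cin, cout, k, stride
        self.pad = (k - 1) // 2 if pad is None else pad
        fan_in = cin * k * k
        scale = np.sqrt(2.0 / fan_in)  # He init for ReLU nets
        self.weight = Param(f"{name}.weight",
                            rng.normal(0.0, scale, (cout, cin * k * k)))
        self.bias = Param(f"{name}.bias", np.zeros(cout)) if bias else None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        k, s, p = self.k, self.stride, self.pad
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        hp, wp = x.shape[2], x.shape[3]
        ho, wo = (hp - k) // s + 1, (wp - k) // s + 1
        win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        # (n, c, ho, wo, k, k) -> (n*ho*wo, c*k*k)
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)
                                    ).reshape(n * ho * wo, c * k * k)
        out = cols @ self.weight.value.T
        if self.bias is not None:
            out += self.bias.value
        self._cache = (cols, (n, c, hp, wp, ho, wo))
        return out.reshape(n, ho, wo, self.cout).transpose(0, 3, 1, 2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        cols, (n, c, hp, wp, ho, wo) = self._cache
        k, s, p = self.k, self.stride, self.pad
        g2 = np.ascontiguousarray(grad.transpose(0, 2, 3, 1)
                                  ).reshape(n * ho * wo, self.cout)
        self.weight.grad += g2.T @ cols
        if self.bias is not None:
            self.bias.grad += g2.sum(axis=0)
        dcols = (g2 @ self.weight.value).reshape(n, ho, wo, c, k, k)
        dxp = np.zeros((n, c, hp, wp))
        for di in range(k):
            for dj in range(k):
                dxp[:, :, di:di + s * ho:s, dj:dj + s * wo:s] += \
                    dcols[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
        if p:
            dxp = dxp[:, :, p:-p, p:-p]
        return dxp

    def parameters(self) -> list[Param]:
        return [self.weight] + ([self.bias] if self.bias is not None else [])


class BatchNorm2d(Layer):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5,
                 name: str = "bn"):
        self.eps, self.momentum = eps, momentum
        self.gamma = Param(f"{name}.gamma", np.ones(c))
        self.beta = Param(f"{name}.beta", np.zeros(c))
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[:, None, None]) * inv[:, None, None]
        self._cache = (xhat, inv, x.shape)
        return self.gamma.value[:, None, None] * xhat + self.beta.value[:, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv, shape = self._cache
        n_eff = shape[0] * shape[2] * shape[3]
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad.sum(axis=(0, 2, 3))
        g = grad * self.gamma.value[:, None, None]
        if not self.training:
            return g * inv[:, None, None]
        gm = g.mean(axis=(0, 2, 3), keepdims=False)
        gxm = (g * xhat).mean(axis=(0, 2, 3))
        del n_eff
        return inv[:, None, None] * (g - gm[:, None, None]
                                     - xhat * gxm[:, None, None])

    def parameters(self) -> list[Param]:
        return [self.gamma, self.beta]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class MaxPool2d(Layer):
    """Max pooling; supports overlapping windows (e.g. 3×3 stride 2, pad 1)."""

    def __init__(self, k: int, stride: int | None = None, pad: int = 0):
        self.k, self.stride, self.pad = k, stride or k, pad

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, s, p = self.k, self.stride, self.pad
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)),
                       constant_values=-np.inf)
        n, c, hp, wp = x.shape
        ho, wo = (hp - k) // s + 1, (wp - k) // s + 1
        win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        flat = win.reshape(n, c, ho, wo, k * k)
        am = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, am[..., None], axis=-1)[..., 0]
        self._cache = (am, (n, c, hp, wp, ho, wo))
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        am, (n, c, hp, wp, ho, wo) = self._cache
        k, s, p = self.k, self.stride, self.pad
        dxp = np.zeros((n, c, hp, wp))
        for pos in range(k * k):
            di, dj = divmod(pos, k)
            contrib = np.where(am == pos, grad, 0.0)
            dxp[:, :, di:di + s * ho:s, dj:dj + s * wo:s] += contrib
        if p:
            dxp = dxp[:, :, p:-p, p:-p]
        return dxp


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(grad[:, :, None, None] / (h * w),
                               self._shape).copy()


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Linear(Layer):
    def __init__(self, fin: int, fout: int, rng: np.random.Generator | None = None,
                 zero_init: bool = False, name: str = "linear"):
        rng = rng or np.random.default_rng(0)
        if zero_init:
            w = np.zeros((fout, fin))
        else:
            w = rng.normal(0.0, np.sqrt(2.0 / fin), (fout, fin))
        self.weight = Param(f"{name}.weight", w)
        self.bias = Param(f"{name}.bias", np.zeros(fout))

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.weight.value.T + self.bias.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.weight.grad += grad.T @ self._x
        self.bias.grad += grad.sum(axis=0)
        return grad @ self.weight.value

    def parameters(self) -> list[Param]:
        return [self.weight, self.bias]


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def parameters(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.parameters()]

    def train(self, mode: bool = True) -> "Sequential":
        self.training = mode
        for layer in self.layers:
            layer.train(mode)
        return self


class BasicBlock(Layer):
    """Two-convolution residual block with optional strided 1×1 downsample."""

    def __init__(self, cin: int, cout: int, stride: int = 1,
                 rng: np.random.Generator | None = None, name: str = "block"):
        rng = rng or np.random.default_rng(0)
        self.conv1 = Conv2d(cin, cout, 3, stride=stride, rng=rng,
                            bias=False, name=f"{name}.conv1")
        self.bn1 = BatchNorm2d(cout, name=f"{name}.bn1")
        self.relu1 = ReLU()
        self.conv2 = Conv2d(cout, cout, 3, rng=rng, bias=False,
                            name=f"{name}.conv2")
        self.bn2 = BatchNorm2d(cout, name=f"{name}.bn2")
        self.relu2 = ReLU()
        if stride != 1 or cin != cout:
            self.down_conv = Conv2d(cin, cout, 1, stride=stride, pad=0,
                                    rng=rng, bias=False, name=f"{name}.down")
            self.down_bn = BatchNorm2d(cout, name=f"{name}.down_bn")
        else:
            self.down_conv = None
            self.down_bn = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        out = self.relu1(self.bn1(self.conv1(x)))
        out = self.bn2(self.conv2(out))
        if self.down_conv is not None:
            shortcut = self.down_bn(self.down_conv(x))
        else:
            shortcut = x
        return self.relu2(out + shortcut)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = self.relu2.backward(grad)
        g_main = self.conv1.backward(self.bn1.backward(self.relu1.backward(
            self.conv2.backward(self.bn2.backward(g)))))
        if self.down_conv is not None:
            g_short = self.down_conv.backward(self.down_bn.backward(g))
        else:
            g_short = g
        return g_main + g_short

    def _sublayers(self) -> list[Layer]:
        subs = [self.conv1, self.bn1, self.relu1, self.conv2, self.bn2,
                self.relu2]
        if self.down_conv is not None:
            subs += [self.down_conv, self.down_bn]
        return subs

    def parameters(self) -> list[Param]:
        return [p for layer in self._sublayers() for p in layer.parameters()]

    def train(self, mode: bool = True) -> "BasicBlock":
        self.training = mode
        for layer in self._sublayers():
            layer.train(mode)
        return self


class SGD:
    def __init__(self, params: list[Param], lr: float, momentum: float = 0.9):
        self.params, self.lr, self.momentum = params, lr, momentum
        self._vel = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        for p, v in zip(self.params, self._vel):
            v *= self.momentum
            v -= self.lr * p.grad
            p.value += v

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


class RMSProp:
    def __init__(self, params: list[Param], lr: float, alpha: float = 0.99,
                 eps: float = 1e-8):
        self.params, self.lr, self.alpha, self.eps = params, lr, alpha, eps
        self._sq = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        for p, s in zip(self.params, self._sq):
            s *= self.alpha
            s += (1 - self.alpha) * p.grad ** 2
            p.value -= self.lr * p.grad / (np.sqrt(s) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


def bce_with_logits(logits: np.ndarray, labels: np.ndarray,
                    weights: np.ndarray | None = None
                    ) -> tuple[float, np.ndarray]:
    """Numerically stable weighted BCE; returns (mean loss, dL/dlogits)."""
    logits = np.asarray(logits, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    if weights is None:
        weights = np.ones_like(labels)
    # log(1+e^x) without overflow
    softplus = np.maximum(logits, 0.0) + np.log1p(np.exp(-np.abs(logits)))
    loss = weights * (softplus - labels * logits)
    grad = weights * (sigmoid(logits) - labels) / labels.size
    return float(loss.mean()), grad


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray
                          ) -> tuple[float, np.ndarray]:
    """Multiclass CE for probe heads; labels are integer class ids."""
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    n = len(labels)
    loss = -np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean()
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return float(loss), grad / n


def mse(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    d = pred.reshape(-1) - np.asarray(target, dtype=np.float64)
    return float((d ** 2).mean()), (2.0 * d / d.size).reshape(pred.shape)


def parameter_checksum(params: list[Param]) -> int:
    """CRC32 over all parameter bytes — cheap identity for provenance."""
    crc = 0
    for p in params:
        crc = zlib.crc32(np.ascontiguousarray(p.value).tobytes(), crc)
    return crc
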