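"""Minimal 1-D convolutional network engine (NumPy, explicit backprop).

Provides exactly the layers the spectral classifier needs: 1-D convolution
(im2col via stride tricks), ReLU, average pooling, squeeze-and-excitation
channel reweighting, dense layers, global average pooling, dropout and a
softmax cross-entropy head, trained with Adam. Arrays are (batch, channels,
length) throughout. The engine is deliberately small: desk-scale spectral
models (tens of thousands of parameters, thousands of length-1000 inputs)
train in seconds through BLAS-backed einsums.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    """Base layer: ``params`` yields (array, grad) pairs for the optimizer."""

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1d(Layer):
    """Same-padded 1-D convolution with optional stride."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int = 1, rng=None):
        if kernel % 2 == 0:
            raise ValueError("kernel size must be odd")
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * kernel
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (c_out, c_in, kernel))
        self.b = np.zeros(c_out)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self.kernel, self.stride = kernel, stride
        self.pad = kernel // 2

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]

    def forward(self, x, train=False):
        n, c, length = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad)))
        cols = sliding_window_view(xp, self.kernel, axis=2)[:, :, :: self.stride]
        self._cols, self._xshape = cols, x.shape
        return np.einsum("nclk,ock->nol", cols, self.w, optimize=True) + self.b[None, :, None]

    def backward(self, grad):
        n, c, length = self._xshape
        self.dw += np.einsum("nclk,nol->ock", self._cols, grad, optimize=True)
        self.db += grad.sum(axis=(0, 2))
        dxp = np.zeros((n, c, length + 2 * self.pad))
        l_out = grad.shape[2]
        pos = self.stride * np.arange(l_out)
        for kk in range(self.kernel):
            contrib = np.einsum("nol,oc->ncl", grad, self.w[:, :, kk], optimize=True)
            if self.stride == 1:
                dxp[:, :, kk : kk + l_out] += contrib
            else:
                # strided positions never collide, so fancy-index add is safe
                dxp[:, :, pos + kk] += contrib
        return dxp[:, :, self.pad : self.pad + length]


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class AvgPool1d(Layer):
    """Non-overlapping average pooling; trailing remainder is dropped."""

    def __init__(self, size: int):
        self.size = size

    def forward(self, x, train=False):
        n, c, length = x.shape
        l_out = length // self.size
        self._in_len = length
        return x[:, :, : l_out * self.size].reshape(n, c, l_out, self.size).mean(axis=3)

    def backward(self, grad):
        n, c, l_out = grad.shape
        dx = np.repeat(grad / self.size, self.size, axis=2)
        if dx.shape[2] < self._in_len:
            dx = np.pad(dx, ((0, 0), (0, 0), (0, self._in_len - dx.shape[2])))
        return dx


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng=None):
        rng = rng or np.random.default_rng(0)
        self.w = rng.normal(0.0, np.sqrt(2.0 / n_in), (n_in, n_out))
        self.b = np.zeros(n_out)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad):
        self.dw += self._x.T @ grad
        self.db += grad.sum(axis=0)
        return grad @ self.w.T


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


class SEBlock(Layer):
    """Squeeze-and-excitation: rescale channels by sigmoid gates in [0, 1].

    Squeeze is a global average over length; excitation is a two-layer
    bottleneck (reduction ratio ``r``) ending in a sigmoid, and the input is
    multiplied channelwise by the resulting gates.
    """

    def __init__(self, channels: int, reduction: int = 4, rng=None):
        hidden = max(channels // reduction, 1)
        self.fc1 = Dense(channels, hidden, rng)
        self.fc2 = Dense(hidden, channels, rng)
        self.relu = ReLU()

    def params(self):
        return self.fc1.params() + self.fc2.params()

    def gates(self, x: np.ndarray) -> np.ndarray:
        z = x.mean(axis=2)
        return _sigmoid(self.fc2.forward(self.relu.forward(self.fc1.forward(z))))

    def forward(self, x, train=False):
        self._x = x
        z = x.mean(axis=2)  # squeeze
        h = self.relu.forward(self.fc1.forward(z), train)
        a = self.fc2.forward(h, train)
        self._s = _sigmoid(a)
        return x * self._s[:, :, None]

    def backward(self, grad):
        x, s = self._x, self._s
        dx = grad * s[:, :, None]
        ds = (grad * x).sum(axis=2)
        da = ds * s * (1.0 - s)
        dz = self.fc1.backward(self.relu.backward(self.fc2.backward(da)))
        dx += dz[:, :, None] / x.shape[2]
        return dx


class Dropout(Layer):
    def __init__(self, rate: float, rng=None):
        self.rate = rate
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x, train=False):
        if not train or self.rate <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = self.rng.binomial(1, keep, size=x.shape) / keep
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class GlobalAvgPool(Layer):
    def forward(self, x, train=False):
        self._length = x.shape[2]
        return x.mean(axis=2)

    def backward(self, grad):
        return np.repeat(grad[:, :, None], self._length, axis=2) / self._length


class ResidualBlock(Layer):
    """Parallel multiscale convolutions, concatenated, SE-gated, plus skip.

    With all branch (and projection-free) weights zeroed the block reduces to
    ``relu(x)`` — the identity map on non-negative inputs, which is the
    domain it sees after the stem ReLU.
    """

    def __init__(self, c_in: int, c_out: int, kernels=(3, 7, 15), se_reduction: int = 4, rng=None):
        rng = rng or np.random.default_rng(0)
        n_br = len(kernels)
        if c_out % n_br:
            raise ValueError("c_out must be divisible by the number of kernel scales")
        self.branches = [Conv1d(c_in, c_out // n_br, k, rng=rng) for k in kernels]
        self.relu1 = ReLU()
        self.se = SEBlock(c_out, se_reduction, rng)
        self.project = Conv1d(c_in, c_out, 1, rng=rng) if c_in != c_out else None
        self.relu2 = ReLU()

    def params(self):
        out = []
        for br in self.branches:
            out += br.params()
        out += self.se.params()
        if self.project is not None:
            out += self.project.params()
        return out

    def forward(self, x, train=False):
        branch_out = np.concatenate([br.forward(x, train) for br in self.branches], axis=1)
        h = self.se.forward(self.relu1.forward(branch_out, train), train)
        skip = x if self.project is None else self.project.forward(x, train)
        self._split = [br.w.shape[0] for br in self.branches]
        return self.relu2.forward(h + skip, train)

    def backward(self, grad):
        g = self.relu2.backward(grad)
        gh = self.relu1.backward(self.se.backward(g))
        dx = g if self.project is None else self.project.backward(g)
        start = 0
        for br, width in zip(self.branches, self._split):
            dx = dx + br.backward(gh[:, start : start + width])
            start += width
        return dx


class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self):
        self.t += 1
        for i, (p, g) in enumerate(self.params):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for _, g in self.params:
            g[...] = 0.0


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_grad(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = len(labels)
    loss = float(-np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean())
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        out = []
        for layer in self.layers:
            out += layer.params()
        return out

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def n_parameters(self) -> int:
        return int(sum(p.size for p, _ in self.params()))
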