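"""Minimal numpy neural-network layers with explicit forward/backward.

Supports exactly what the densely connected patch classifier needs:
im2col-based 2-D convolution, batch normalization with running statistics,
ReLU, max/average pooling, global average pooling, linear layers,
dense blocks with feature concatenation, and transition layers.

Initialization conventions: convolution weights are Kaiming-normal
(fan-in, ReLU gain), linear weights and biases are uniform on
[-1/sqrt(fan_in), 1/sqrt(fan_in)], batch-norm scale/shift start at 1/0.
All arrays are float32 NCHW (single precision is bit-deterministic and
halves the memory traffic of the im2col path).
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "Parameter",
    "Module",
    "Sequential",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2d",
    "AvgPool2d",
    "GlobalAvgPool",
    "Flatten",
    "Linear",
    "DenseLayer",
    "DenseBlock",
    "Transition",
]


class Parameter:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.ascontiguousarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)


class Module:
    training: bool = True

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)

    # -- recursive traversal -------------------------------------------------
    def children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                yield prefix + name, value
        for name, child in self.children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = ""):
        for name in getattr(self, "_buffers", ()):
            yield prefix + name, getattr(self, name)
        for name, child in self.children():
            yield from child.named_buffers(prefix + name + ".")

    def set_training(self, flag: bool) -> None:
        self.training = flag
        for _, child in self.children():
            child.set_training(flag)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    # -- (de)serialization ---------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({name: b.copy() for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        missing = (set(params) | set(buffers)) - set(state)
        if missing:
            raise KeyError(f"state dict missing entries: {sorted(missing)[:5]}")
        for name, p in params.items():
            p.data[...] = state[name]
        for name, b in buffers.items():
            b[...] = state[name]


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


# ---------------------------------------------------------------------------
# im2col helpers


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int,
            pad_value: float = 0.0):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)),
                   constant_values=pad_value)
    hp, wp = h + 2 * pad, w + 2 * pad
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    s0, s1, s2, s3 = x.strides
    view = np.lib.stride_tricks.as_strided(
        x, (n, c, kh, kw, ho, wo), (s0, s1, s2, s3, s2 * stride, s3 * stride))
    # (n*ho*wo, c*kh*kw)
    cols = view.transpose(0, 4, 5, 1, 2, 3).reshape(n * ho * wo, c * kh * kw)
    return np.ascontiguousarray(cols), ho, wo


def _col2im(dcols: np.ndarray, x_shape, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    dpatches = dcols.reshape(n, ho, wo, c, kh, kw).transpose(0, 3, 4, 5, 1, 2)
    dx = np.zeros((n, c, hp, wp), dtype=dcols.dtype)
    for i in range(kh):
        for j in range(kw):
            dx[:, :, i: i + stride * ho: stride, j: j + stride * wo: stride] += \
                dpatches[:, :, i, j]
    if pad:
        dx = dx[:, :, pad:-pad, pad:-pad]
    return dx


class Conv2d(Module):
    """2-D convolution, bias-free (batch norm always follows it here)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 pad: int = 0, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        fan_in = in_ch * kernel * kernel
        std = math.sqrt(2.0 / fan_in)  # Kaiming, ReLU gain
        self.weight = Parameter(rng.normal(0.0, std, (out_ch, in_ch, kernel, kernel)))
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride, self.pad = kernel, stride, pad
        self._cache = None

    def forward(self, x):
        cols, ho, wo = _im2col(x, self.kernel, self.kernel, self.stride, self.pad)
        wmat = self.weight.data.reshape(self.out_ch, -1)
        out = cols @ wmat.T
        self._cache = (x.shape, cols)
        # contiguous output keeps the following batch-norm/ReLU passes fast
        return np.ascontiguousarray(
            out.reshape(x.shape[0], ho, wo, self.out_ch).transpose(0, 3, 1, 2))

    def backward(self, grad):
        x_shape, cols = self._cache
        n = grad.shape[0]
        gcols = grad.transpose(0, 2, 3, 1).reshape(-1, self.out_ch)
        self.weight.grad += (gcols.T @ cols).reshape(self.weight.data.shape)
        dcols = gcols @ self.weight.data.reshape(self.out_ch, -1)
        return _col2im(dcols, x_shape, self.kernel, self.kernel,
                       self.stride, self.pad)


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.weight = Parameter(np.ones(channels))
        self.bias = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self._buffers = ("running_mean", "running_var")
        self.eps, self.momentum = eps, momentum
        self._cache = None

    def forward(self, x):
        if self.training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = x.shape[0] * x.shape[2] * x.shape[3]
            self.running_mean += self.momentum * (mean - self.running_mean)
            unbiased = var * m / max(m - 1, 1)
            self.running_var += self.momentum * (unbiased - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        self._cache = (xhat, inv_std)
        return self.weight.data[None, :, None, None] * xhat + \
            self.bias.data[None, :, None, None]

    def backward(self, grad):
        xhat, inv_std = self._cache
        axes = (0, 2, 3)
        self.weight.grad += (grad * xhat).sum(axis=axes)
        self.bias.grad += grad.sum(axis=axes)
        gxhat = grad * self.weight.data[None, :, None, None]
        if not self.training:
            return gxhat * inv_std[None, :, None, None]
        m = grad.shape[0] * grad.shape[2] * grad.shape[3]
        term = gxhat - gxhat.mean(axis=axes, keepdims=True) \
            - xhat * (gxhat * xhat).mean(axis=axes, keepdims=True)
        return term * inv_std[None, :, None, None]


class ReLU(Module):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class MaxPool2d(Module):
    def __init__(self, kernel: int, stride: int, pad: int = 0):
        self.kernel, self.stride, self.pad = kernel, stride, pad

    def forward(self, x):
        cols, ho, wo = _im2col(
            x.reshape(-1, 1, *x.shape[2:]), self.kernel, self.kernel,
            self.stride, self.pad, pad_value=-np.inf)
        self._argmax = cols.argmax(axis=1)
        self._x_shape = x.shape
        out = cols[np.arange(cols.shape[0]), self._argmax]
        n, c = x.shape[:2]
        return out.reshape(n, c, ho, wo)

    def backward(self, grad):
        n, c, h, w = self._x_shape
        k2 = self.kernel * self.kernel
        dcols = np.zeros((self._argmax.size, k2), dtype=grad.dtype)
        dcols[np.arange(self._argmax.size), self._argmax] = grad.ravel()
        dx = _col2im(dcols, (n * c, 1, h, w), self.kernel, self.kernel,
                     self.stride, self.pad)
        return dx.reshape(n, c, h, w)


class AvgPool2d(Module):
    def __init__(self, kernel: int = 2, stride: int | None = None):
        self.kernel = kernel
        self.stride = stride or kernel

    def forward(self, x):
        cols, ho, wo = _im2col(x.reshape(-1, 1, *x.shape[2:]),
                               self.kernel, self.kernel, self.stride, 0)
        self._x_shape = x.shape
        n, c = x.shape[:2]
        return cols.mean(axis=1).reshape(n, c, ho, wo)

    def backward(self, grad):
        n, c, h, w = self._x_shape
        k2 = self.kernel * self.kernel
        dcols = np.repeat(grad.reshape(-1, 1), k2, axis=1) / k2
        dx = _col2im(dcols, (n * c, 1, h, w), self.kernel, self.kernel,
                     self.stride, 0)
        return dx.reshape(n, c, h, w)


class GlobalAvgPool(Module):
    def forward(self, x):
        self._spatial = x.shape[2] * x.shape[3]
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        n, c, h, w = self._shape
        return np.broadcast_to(grad[:, :, None, None] / self._spatial,
                               (n, c, h, w)).copy()


class Flatten(Module):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        bound = 1.0 / math.sqrt(in_features)
        self.weight = Parameter(rng.uniform(-bound, bound, (out_features, in_features)))
        self.bias = Parameter(rng.uniform(-bound, bound, out_features))

    def forward(self, x):
        self._x = x
        return x @ self.weight.data.T + self.bias.data

    def backward(self, grad):
        self.weight.grad += grad.T @ self._x
        self.bias.grad += grad.sum(axis=0)
        return grad @ self.weight.data


class DenseLayer(Module):
    """BN-ReLU-1x1 conv (bottleneck) -> BN-ReLU-3x3 conv, output concatenated
    onto the input features."""

    def __init__(self, in_ch: int, growth: int, bn_size: int,
                 rng: np.random.Generator):
        inter = bn_size * growth
        self.in_ch = in_ch
        self.body = Sequential(
            BatchNorm2d(in_ch), ReLU(), Conv2d(in_ch, inter, 1, rng=rng),
            BatchNorm2d(inter), ReLU(), Conv2d(inter, growth, 3, pad=1, rng=rng),
        )

    def forward(self, x):
        new = self.body(x)
        return np.concatenate([x, new], axis=1)

    def backward(self, grad):
        gx, gnew = grad[:, : self.in_ch], grad[:, self.in_ch:]
        return gx + self.body.backward(np.ascontiguousarray(gnew))


class DenseBlock(Module):
    def __init__(self, in_ch: int, n_layers: int, growth: int, bn_size: int,
                 rng: np.random.Generator):
        self.layers = [DenseLayer(in_ch + i * growth, growth, bn_size, rng)
                       for i in range(n_layers)]
        self.out_ch = in_ch + n_layers * growth

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


class Transition(Module):
    """BN-ReLU-1x1 conv channel compression followed by 2x2 average pooling,
    halving the spatial resolution between dense blocks."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        self.body = Sequential(BatchNorm2d(in_ch), ReLU(),
                               Conv2d(in_ch, out_ch, 1, rng=rng), AvgPool2d(2))
        self.out_ch = out_ch

    def forward(self, x):
        return self.body(x)

    def backward(self, grad):
        return self.body.backward(grad)
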