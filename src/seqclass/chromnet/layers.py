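"""Minimal NumPy neural-network layers with manual backpropagation.

Tensors are ``float64`` arrays shaped ``(batch, channels, length)`` for
spatial layers and ``(batch, features)`` after flattening. Each layer
caches what it needs during ``forward`` and consumes it in ``backward``.
Parameters are exposed as named slots so optimizers and checkpoints can
address them uniformly.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

__all__ = [
    "Layer",
    "Conv1d",
    "ReLU",
    "MaxPool1d",
    "SplineTransform",
    "Flatten",
    "Dense",
    "DualPathBlock",
    "DilatedResidualBlock",
    "Sequential",
]


class Layer:
    """Base class: parameter-free identity."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def parameters(self) -> dict[str, np.ndarray]:
        return {}

    def gradients(self) -> dict[str, np.ndarray]:
        return {}

    def buffers(self) -> dict[str, np.ndarray]:
        """Non-trainable state (e.g. normalization running statistics)."""
        return {}

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters().values())


class Conv1d(Layer):
    """1-D convolution with 'same' zero padding and optional dilation.

    Computed as a sum of per-tap shifted matmuls — one small GEMM per
    kernel tap — which avoids materializing an im2col buffer and keeps
    both passes cache-friendly for the short kernels used here.
    """

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int,
        dilation: int = 1,
        rng: Optional[np.random.Generator] = None,
        init_scale: Optional[float] = None,
    ):
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd for 'same' padding")
        rng = rng if rng is not None else np.random.default_rng(0)
        self.c_in, self.c_out, self.kernel, self.dilation = c_in, c_out, kernel, dilation
        scale = init_scale if init_scale is not None else np.sqrt(2.0 / (c_in * kernel))
        # weight layout: (kernel, c_out, c_in), one matrix per tap
        self.W = rng.normal(0.0, scale, size=(kernel, c_out, c_in))
        self.b = np.zeros(c_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache: Optional[tuple] = None

    @property
    def pad(self) -> int:
        return self.dilation * (self.kernel - 1) // 2

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, length = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} channels, got {c}")
        p = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p)))
        out = np.empty((n, self.c_out, length))
        out[:] = self.b[:, None]
        for k in range(self.kernel):
            off = self.dilation * k
            out += np.matmul(self.W[k], xp[:, :, off : off + length])
        if train:
            self._cache = (xp, length)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        assert self._cache is not None, "backward called before forward(train=True)"
        xp, length = self._cache
        self.db = grad.sum(axis=(0, 2))
        dxp = np.zeros_like(xp)
        for k in range(self.kernel):
            off = self.dilation * k
            xs = xp[:, :, off : off + length]
            # (c_out, c_in) accumulated over batch and length
            self.dW[k] = np.tensordot(grad, xs, axes=([0, 2], [0, 2]))
            dxp[:, :, off : off + length] += np.matmul(self.W[k].T, grad)
        p = self.pad
        self._cache = None
        return dxp[:, :, p : p + length]

    def parameters(self) -> dict[str, np.ndarray]:
        return {"W": self.W, "b": self.b}

    def gradients(self) -> dict[str, np.ndarray]:
        return {"W": self.dW, "b": self.db}


class BatchNorm1d(Layer):
    """Per-channel batch normalization over (batch, length) with running
    statistics for inference."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.dgamma = np.zeros(channels)
        self.dbeta = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mean
            self.running_var = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[:, None]) * inv_std[:, None]
        if train:
            self._cache = (xhat, inv_std)
        return self.gamma[:, None] * xhat + self.beta[:, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        n = grad.shape[0] * grad.shape[2]
        self.dgamma = (grad * xhat).sum(axis=(0, 2))
        self.dbeta = grad.sum(axis=(0, 2))
        dxhat = grad * self.gamma[:, None]
        return (
            inv_std[:, None]
            / n
            * (
                n * dxhat
                - dxhat.sum(axis=(0, 2))[:, None]
                - xhat * (dxhat * xhat).sum(axis=(0, 2))[:, None]
            )
        )

    def parameters(self) -> dict[str, np.ndarray]:
        return {"gamma": self.gamma, "beta": self.beta}

    def gradients(self) -> dict[str, np.ndarray]:
        return {"gamma": self.dgamma, "beta": self.dbeta}

    def buffers(self) -> dict[str, np.ndarray]:
        return {"running_mean": self.running_mean, "running_var": self.running_var}


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class MaxPool1d(Layer):
    """Non-overlapping max pooling; the spatial length must be divisible
    by the pooling factor."""

    def __init__(self, factor: int):
        if factor < 1:
            raise ValueError("pool factor must be >= 1")
        self.factor = factor

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, length = x.shape
        if length % self.factor:
            raise ValueError(
                f"length {length} not divisible by pool factor {self.factor}"
            )
        xr = x.reshape(n, c, length // self.factor, self.factor)
        out = xr.max(axis=3)
        if train:
            self._argmax = xr.argmax(axis=3)
            self._in_shape = x.shape
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, lout = grad.shape
        dx = np.zeros((n, c, lout, self.factor))
        np.put_along_axis(dx, self._argmax[..., None], grad[..., None], axis=3)
        return dx.reshape(self._in_shape)


class SplineTransform(Layer):
    """Multiply the spatial axis by a fixed basis matrix (bins x df),
    reducing ``(n, c, bins)`` to ``(n, c, df)``. The basis has no trainable
    parameters."""

    def __init__(self, basis: np.ndarray):
        self.basis = np.asarray(basis, dtype=float)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.shape[2] != self.basis.shape[0]:
            raise ValueError(
                f"expected {self.basis.shape[0]} spatial bins, got {x.shape[2]}"
            )
        return x @ self.basis

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad @ self.basis.T


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: Optional[np.random.Generator] = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.n_in, self.n_out = n_in, n_out
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_out, n_in))
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.W.T + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.dW = grad.T @ self._x
        self.db = grad.sum(axis=0)
        return grad @ self.W

    def parameters(self) -> dict[str, np.ndarray]:
        return {"W": self.W, "b": self.b}

    def gradients(self) -> dict[str, np.ndarray]:
        return {"W": self.dW, "b": self.db}


class DualPathBlock(Layer):
    """A linear convolution feeding a residual nonlinear path.

    ``y = linear(x); out = y + relu(bn(nonlinear(y)))`` — the linear block
    has no activation so linear dependencies pass straight through, while
    the normalized nonlinear branch adds representation power on top. With
    the nonlinear convolution zeroed (weights and bias) the branch emits
    exactly zero, so the block reduces bit-exactly to its linear path.
    """

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int,
        rng: Optional[np.random.Generator] = None,
    ):
        self.linear = Conv1d(c_in, c_out, kernel, rng=rng)
        self.nonlinear = Conv1d(c_out, c_out, kernel, rng=rng)
        self.bn = BatchNorm1d(c_out)
        self.relu = ReLU()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        y = self.linear.forward(x, train)
        z = self.relu.forward(
            self.bn.forward(self.nonlinear.forward(y, train), train), train
        )
        return y + z

    def backward(self, grad: np.ndarray) -> np.ndarray:
        dz = self.bn.backward(self.relu.backward(grad))
        dy = grad + self.nonlinear.backward(dz)
        return self.linear.backward(dy)

    def _parts(self):
        return {"linear": self.linear, "nonlinear": self.nonlinear, "bn": self.bn}

    def parameters(self) -> dict[str, np.ndarray]:
        return {
            f"{name}.{k}": v
            for name, part in self._parts().items()
            for k, v in part.parameters().items()
        }

    def gradients(self) -> dict[str, np.ndarray]:
        return {
            f"{name}.{k}": v
            for name, part in self._parts().items()
            for k, v in part.gradients().items()
        }

    def buffers(self) -> dict[str, np.ndarray]:
        return {f"bn.{k}": v for k, v in self.bn.buffers().items()}


class DilatedResidualBlock(Layer):
    """``out = x + relu(bn(conv_dilated(x)))``: grows the receptive field
    without shrinking the spatial axis."""

    def __init__(
        self,
        channels: int,
        kernel: int,
        dilation: int,
        rng: Optional[np.random.Generator] = None,
    ):
        self.conv = Conv1d(channels, channels, kernel, dilation=dilation, rng=rng)
        self.bn = BatchNorm1d(channels)
        self.relu = ReLU()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return x + self.relu.forward(
            self.bn.forward(self.conv.forward(x, train), train), train
        )

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad + self.conv.backward(self.bn.backward(self.relu.backward(grad)))

    def parameters(self) -> dict[str, np.ndarray]:
        out = {f"conv.{k}": v for k, v in self.conv.parameters().items()}
        out.update({f"bn.{k}": v for k, v in self.bn.parameters().items()})
        return out

    def gradients(self) -> dict[str, np.ndarray]:
        out = {f"conv.{k}": v for k, v in self.conv.gradients().items()}
        out.update({f"bn.{k}": v for k, v in self.bn.gradients().items()})
        return out

    def buffers(self) -> dict[str, np.ndarray]:
        return {f"bn.{k}": v for k, v in self.bn.buffers().items()}


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def parameters(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.layers):
            for k, v in layer.parameters().items():
                out[f"{i}.{k}"] = v
        return out

    def gradients(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.layers):
            for k, v in layer.gradients().items():
                out[f"{i}.{k}"] = v
        return out

    def buffers(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.layers):
            for k, v in layer.buffers().items():
                out[f"{i}.{k}"] = v
        return out

    def set_parameters(self, values: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if set(values) != set(params):
            missing = set(params) ^ set(values)
            raise KeyError(f"parameter name mismatch: {sorted(missing)}")
        for name, arr in values.items():
            params[name][...] = arr

    def set_buffers(self, values: dict[str, np.ndarray]) -> None:
        buffers = self.buffers()
        for name, arr in values.items():
            buffers[name][...] = arr
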