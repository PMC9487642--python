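"""Minimal CPU layer library with explicit forward/backward passes.

Layers cache per-call state on a stack, so a weight-shared trunk may be run
forward several times per step (once per family member) and backpropagated
in reverse order of the forward calls.  Gradients accumulate into ``grad``
buffers until :func:`zero_grad`.

Shapes follow the (batch, channels, height, width) convention; "height" is
the reference window axis and "width" the read-depth axis of the pileup
tensors.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32  # training dtype; float64 buys nothing for SGD here

__all__ = [
    "Param",
    "Layer",
    "Sequential",
    "Conv2d",
    "ReLU",
    "ResBlock",
    "PyramidPool",
    "Flatten",
    "Dense",
]


class Param:
    """A trainable array with an accumulating gradient buffer."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)


class Layer:
    def __init__(self) -> None:
        self._stack: list = []

    @property
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        super().__init__()
        self.layers = list(layers)

    @property
    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        mask = x > 0
        self._stack.append(mask)
        return x * mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._stack.pop()


class Conv2d(Layer):
    """Same-padded stride-1 2-D convolution via im2col."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        fan_in = c_in * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)
        self.kernel = kernel
        self.c_in, self.c_out = c_in, c_out
        self.w = Param(rng.normal(0.0, scale, size=(fan_in, c_out)))
        self.b = Param(np.zeros(c_out))

    @property
    def params(self) -> list[Param]:
        return [self.w, self.b]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        k = self.kernel
        pad = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        # (B, C, H, W, k, k) -> (B, H, W, C*k*k)
        cols = sliding_window_view(xp, (k, k), axis=(2, 3))
        return np.ascontiguousarray(cols.transpose(0, 2, 3, 1, 4, 5)).reshape(
            x.shape[0], x.shape[2], x.shape[3], -1
        )

    def forward(self, x: np.ndarray) -> np.ndarray:
        cols = self._im2col(x)
        self._stack.append((x.shape, cols))
        y = cols @ self.w.value + self.b.value
        return y.transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x_shape, cols = self._stack.pop()
        b, _, h, w = x_shape
        dyt = dy.transpose(0, 2, 3, 1)  # (B, H, W, Cout)
        flat_cols = cols.reshape(-1, cols.shape[-1])
        flat_dy = dyt.reshape(-1, self.c_out)
        self.w.grad += flat_cols.T @ flat_dy
        self.b.grad += flat_dy.sum(axis=0)
        # fold the column gradient back: loop over the k*k kernel offsets
        dcols = (flat_dy @ self.w.value.T).reshape(b, h, w, self.c_in, self.kernel, self.kernel)
        k = self.kernel
        pad = k // 2
        dxp = np.zeros((b, self.c_in, h + 2 * pad, w + 2 * pad), dtype=dy.dtype)
        for di in range(k):
            for dj in range(k):
                dxp[:, :, di : di + h, dj : dj + w] += dcols[:, :, :, :, di, dj].transpose(
                    0, 3, 1, 2
                )
        return dxp[:, :, pad : pad + h, pad : pad + w]


class ResBlock(Layer):
    """Two same-channel convolutions with an identity skip: relu(x + F(x))."""

    def __init__(self, channels: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = Conv2d(channels, channels, kernel, rng)
        self.relu = ReLU()
        self.conv2 = Conv2d(channels, channels, kernel, rng)
        self.out_relu = ReLU()

    @property
    def params(self) -> list[Param]:
        return self.conv1.params + self.conv2.params

    def forward(self, x: np.ndarray) -> np.ndarray:
        y = self.conv2.forward(self.relu.forward(self.conv1.forward(x)))
        return self.out_relu.forward(x + y)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d = self.out_relu.backward(dy)
        dx_branch = self.conv1.backward(self.relu.backward(self.conv2.backward(d)))
        return d + dx_branch


class PyramidPool(Layer):
    """Spatial pyramid pooling: adaptive average pools at several bin grids.

    Maps (B, C, H, W) to (B, C * sum(b*b for b in bins)) regardless of the
    spatial extent, decoupling the dense stack from window/depth sizes.
    """

    def __init__(self, bins: tuple[int, ...] = (1, 2, 4)):
        super().__init__()
        self.bins = tuple(bins)

    @staticmethod
    def _edges(size: int, nbin: int) -> np.ndarray:
        return np.floor(np.linspace(0, size, nbin + 1)).astype(int)

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        outs = []
        regions = []
        for nb in self.bins:
            he = self._edges(h, nb)
            we = self._edges(w, nb)
            for i in range(nb):
                for j in range(nb):
                    h0, h1 = he[i], max(he[i + 1], he[i] + 1)
                    w0, w1 = we[j], max(we[j + 1], we[j] + 1)
                    outs.append(x[:, :, h0:h1, w0:w1].mean(axis=(2, 3)))
                    regions.append((h0, h1, w0, w1))
        self._stack.append((x.shape, regions))
        return np.stack(outs, axis=2).reshape(b, -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x_shape, regions = self._stack.pop()
        b, c = x_shape[:2]
        dy = dy.reshape(b, c, len(regions))
        dx = np.zeros(x_shape, dtype=dy.dtype)
        for r, (h0, h1, w0, w1) in enumerate(regions):
            area = (h1 - h0) * (w1 - w0)
            dx[:, :, h0:h1, w0:w1] += dy[:, :, r, None, None] / area
        return dx


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._stack.append(x.shape)
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._stack.pop())


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / n_in)
        self.w = Param(rng.normal(0.0, scale, size=(n_in, n_out)))
        self.b = Param(np.zeros(n_out))

    @property
    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._stack.append(x)
        return x @ self.w.value + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._stack.pop()
        self.w.grad += x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.w.value.T
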