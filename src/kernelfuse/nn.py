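"""Minimal NumPy neural-network core for the kernel-synthesis U-Net.

Self-contained forward/backward layers: 3x3 same-padding convolutions via
im2col matrix multiplication, ReLU, 2x2 average pooling, nearest-neighbour
upsampling, and an Adam optimizer. All activations are float32 in
channels-last (B, H, W, C) layout, which lets the im2col patch matrix be
assembled from nine contiguous slice copies instead of a strided gather.
Each layer caches what its backward pass needs (convolutions keep only their
input and rebuild the patch matrix on demand), so usage is strictly
forward-then-backward per step on a single thread.

The input gradient of a convolution is computed as another 3x3 convolution
with the spatially flipped, channel-transposed weights, which keeps the
whole backward pass inside the same matmul machinery.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv3x3", "Conv1x1", "ReLU", "AvgPool2", "Upsample2", "Adam", "glorot_uniform"]


def glorot_uniform(rng: np.random.Generator, c_in: int, c_out: int, k: int = 3) -> np.ndarray:
    """Glorot/Xavier uniform initialization for a (k, k, c_in, c_out) kernel."""
    fan_in, fan_out = c_in * k * k, c_out * k * k
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(k, k, c_in, c_out)).astype(np.float32)


_OFFSETS = [(i, j) for i in range(3) for j in range(3)]


def _conv3x3_raw(x: np.ndarray, weight: np.ndarray, bias=None) -> np.ndarray:
    """Plain 3x3 convolution as nine shifted matmuls; weight layout (3, 3, C_in, C_out).

    Each kernel offset contributes one contiguous-buffer copy plus one GEMM,
    which is far cheaper on a CPU than a strided im2col gather.
    """
    b, h, w, c = x.shape
    c_out = weight.shape[-1]
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    buf = np.empty((b, h, w, c), dtype=x.dtype)
    flat = buf.reshape(b * h * w, c)
    tmp = np.empty((b * h * w, c_out), dtype=x.dtype)
    y = np.zeros((b * h * w, c_out), dtype=x.dtype)
    for i, j in _OFFSETS:
        np.copyto(buf, xp[:, i:i + h, j:j + w, :])
        np.matmul(flat, weight[i, j], out=tmp)
        y += tmp
    if bias is not None:
        y += bias
    return y.reshape(b, h, w, c_out)


class Conv3x3:
    """3x3 convolution, stride 1, zero same-padding, with bias."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator | None = None,
                 zero_init: bool = False):
        self.c_in, self.c_out = c_in, c_out
        if zero_init:
            self.weight = np.zeros((3, 3, c_in, c_out), dtype=np.float32)
        else:
            if rng is None:
                raise ValueError("rng required unless zero_init")
            self.weight = glorot_uniform(rng, c_in, c_out)
        self.bias = np.zeros(c_out, dtype=np.float32)
        self.grad_weight = np.zeros_like(self.weight)
        self.grad_bias = np.zeros_like(self.bias)
        self._x = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._x = x if train else None
        return _conv3x3_raw(x, self.weight, self.bias)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, h, w, c_out = dy.shape
        dy_r = dy.reshape(b * h * w, c_out)
        x = self._x
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        buf = np.empty_like(x)
        flat = buf.reshape(b * h * w, x.shape[-1])
        for i, j in _OFFSETS:
            np.copyto(buf, xp[:, i:i + h, j:j + w, :])
            self.grad_weight[i, j] += flat.T @ dy_r
        self.grad_bias += dy_r.sum(axis=0)
        self._x = None
        # dx = conv of dy with the flipped, in/out-transposed kernel
        w_t = np.ascontiguousarray(self.weight[::-1, ::-1].transpose(0, 1, 3, 2))
        return _conv3x3_raw(dy, w_t)

    def parameters(self):
        return [(self.weight, self.grad_weight), (self.bias, self.grad_bias)]


class Conv1x1:
    """1x1 convolution (per-pixel linear map); used to fuse skip connections."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.c_in, self.c_out = c_in, c_out
        self.weight = glorot_uniform(rng, c_in, c_out, k=1)[0, 0]
        self.bias = np.zeros(c_out, dtype=np.float32)
        self.grad_weight = np.zeros_like(self.weight)
        self.grad_bias = np.zeros_like(self.bias)
        self._x = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._x = x if train else None
        y = x.reshape(-1, self.c_in) @ self.weight + self.bias
        return y.reshape(*x.shape[:-1], self.c_out)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy_r = dy.reshape(-1, self.c_out)
        x_r = self._x.reshape(-1, self.c_in)
        self.grad_weight += x_r.T @ dy_r
        self.grad_bias += dy_r.sum(axis=0)
        self._x = None
        return (dy_r @ self.weight.T).reshape(*dy.shape[:-1], self.c_in)

    def parameters(self):
        return [(self.weight, self.grad_weight), (self.bias, self.grad_bias)]


class ReLU:
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        y = np.maximum(x, 0.0)
        self._mask = x > 0 if train else None
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask

    def parameters(self):
        return []


class AvgPool2:
    """2x2 average pooling; spatial dims must be even."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        b, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError("AvgPool2 needs even spatial dimensions")
        return x.reshape(b, h // 2, 2, w // 2, 2, c).mean(axis=(2, 4))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.repeat(np.repeat(dy, 2, axis=1), 2, axis=2) * 0.25

    def parameters(self):
        return []


class Upsample2:
    """Nearest-neighbour 2x upsampling."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, h, w, c = dy.shape
        return dy.reshape(b, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))

    def parameters(self):
        return []


class Adam:
    """Adam optimizer over (value, grad) parameter pairs."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in self.params]
        self.v = [np.zeros_like(p) for p, _ in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for i, (p, g) in enumerate(self.params):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            p -= self.lr * (self.m[i] / bc1) / (np.sqrt(self.v[i] / bc2) + self.eps)

    def zero_grad(self) -> None:
        for _, g in self.params:
            g[...] = 0.0
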