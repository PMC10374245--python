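"""Minimal NumPy neural-network core: layers with explicit forward/backward
passes and an Adam optimizer.

Only the pieces the dual-branch model needs are implemented: channel-axis
2-D convolution (kernel width 1), ELU, adaptive average pooling, fully
connected layers, per-sample L2 normalization, and softmax cross-entropy.
All arithmetic is float32; every layer caches what its backward pass needs.
"""

from __future__ import annotations

import math

import numpy as np

DTYPE = np.float32


class Param:
    """A trainable array plus its accumulated gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.ascontiguousarray(data, dtype=DTYPE)
        self.grad = np.zeros_like(self.data)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def _uniform_fan_in(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = 1.0 / math.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


class Layer:
    def parameters(self) -> list[Param]:
        return []


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.n_in, self.n_out = n_in, n_out
        self.W = Param(_uniform_fan_in(rng, (n_in, n_out), n_in))
        self.b = Param(_uniform_fan_in(rng, (n_out,), n_in))
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[-1] != self.n_in:
            raise ValueError(
                f"Linear layer expected input width {self.n_in}, got {x.shape[-1]}"
            )
        self._x = x
        return x @ self.W.data + self.b.data

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.W.data.T

    def parameters(self) -> list[Param]:
        return [self.W, self.b]


class ELU(Layer):
    """Exponential linear unit, alpha = 1."""

    def __init__(self) -> None:
        self._e: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        # y = max(x,0) + expm1(min(x,0)); the negative-side exponential e
        # doubles as the derivative cache (dELU/dx = e + 1 everywhere)
        e = np.expm1(np.minimum(x, 0.0, dtype=DTYPE))
        self._e = e
        return np.maximum(x, 0.0, dtype=DTYPE) + e

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * (self._e + 1.0)


class ConvChannel(Layer):
    """2-D convolution whose kernel spans only the channel (height) axis.

    Kernel shape is (k, 1) with stride (s, 1) and no padding, so each time
    sample is convolved independently: out[b, o, h, t] =
    sum_{c,j} x[b, c, h*s + j, t] * W[o, c, j] + bias[o].
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int,
                 rng: np.random.Generator):
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride = kernel, stride
        fan_in = in_ch * kernel
        self.W = Param(_uniform_fan_in(rng, (out_ch, in_ch, kernel), fan_in))
        self.b = Param(_uniform_fan_in(rng, (out_ch,), fan_in))
        self._segs: list[np.ndarray] | None = None
        self._xshape: tuple | None = None

    def out_height(self, in_height: int) -> int:
        return (in_height - self.kernel) // self.stride + 1

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, H, T = x.shape
        if C != self.in_ch:
            raise ValueError(
                f"ConvChannel expected {self.in_ch} input maps, got {C}"
            )
        Ho = self.out_height(H)
        if Ho < 1:
            raise ValueError(
                f"input height {H} too small for kernel {self.kernel}"
            )
        # one batched GEMM per output height row: (O, C*k) @ (B, C*k, T)
        wmat = self.W.data.reshape(self.out_ch, C * self.kernel)
        segs = []
        y = np.empty((B, self.out_ch, Ho, T), dtype=DTYPE)
        for h in range(Ho):
            seg = x[:, :, h * self.stride: h * self.stride + self.kernel, :]
            seg = np.ascontiguousarray(seg).reshape(B, C * self.kernel, T)
            segs.append(seg)
            np.matmul(wmat, seg, out=y[:, :, h, :])
        y += self.b.data[None, :, None, None]
        self._segs, self._xshape = segs, (B, C, H, T, Ho)
        return y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        B, C, H, T, Ho = self._xshape
        wmat = self.W.data.reshape(self.out_ch, C * self.kernel)
        dwmat = np.zeros_like(wmat)
        dx = np.zeros((B, C, H, T), dtype=DTYPE)
        for h in range(Ho):
            g = np.ascontiguousarray(grad[:, :, h, :])  # (B, O, T)
            seg = self._segs[h]  # (B, C*k, T)
            # dW += sum_b g_b @ seg_b^T
            dwmat += np.einsum("bot,bct->oc", g, seg, optimize=True)
            dseg = np.matmul(wmat.T, g)  # (B, C*k, T)
            dx[:, :, h * self.stride: h * self.stride + self.kernel, :] += (
                dseg.reshape(B, C, self.kernel, T)
            )
        self.W.grad += dwmat.reshape(self.W.data.shape)
        self.b.grad += grad.sum(axis=(0, 2, 3))
        return dx

    def parameters(self) -> list[Param]:
        return [self.W, self.b]


def _pool_bins(n_in: int, n_out: int) -> list[tuple[int, int]]:
    """Adaptive-pool bin boundaries: bin i covers
    [floor(i*n_in/n_out), ceil((i+1)*n_in/n_out))."""
    return [
        (i * n_in // n_out, -(-(i + 1) * n_in // n_out))
        for i in range(n_out)
    ]


class AdaptiveAvgPool2d(Layer):
    """Average pooling to a fixed output grid; bins may overlap or repeat
    when the output is larger than the input along an axis."""

    def __init__(self, out_h: int, out_w: int):
        self.out_h, self.out_w = out_h, out_w
        self._in_shape: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, H, W = x.shape
        self._in_shape = x.shape
        hb = _pool_bins(H, self.out_h)
        wb = _pool_bins(W, self.out_w)
        y = np.empty((B, C, self.out_h, self.out_w), dtype=DTYPE)
        for i, (h0, h1) in enumerate(hb):
            for j, (w0, w1) in enumerate(wb):
                y[:, :, i, j] = x[:, :, h0:h1, w0:w1].mean(axis=(2, 3))
        return y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        B, C, H, W = self._in_shape
        hb = _pool_bins(H, self.out_h)
        wb = _pool_bins(W, self.out_w)
        dx = np.zeros(self._in_shape, dtype=DTYPE)
        for i, (h0, h1) in enumerate(hb):
            for j, (w0, w1) in enumerate(wb):
                area = (h1 - h0) * (w1 - w0)
                dx[:, :, h0:h1, w0:w1] += grad[:, :, i, j, None, None] / area
        return dx


class L2Normalize(Layer):
    """Scale each row of a (B, D) matrix to unit Euclidean norm."""

    def __init__(self, eps: float = 1e-12):
        self.eps = eps
        self._y: np.ndarray | None = None
        self._norm: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        norm = np.linalg.norm(x, axis=1, keepdims=True)
        if np.any(norm < self.eps):
            raise ValueError("cannot L2-normalize a zero-norm representation")
        y = x / norm
        self._y, self._norm = y, norm
        return y.astype(DTYPE, copy=False)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        dot = (grad * self._y).sum(axis=1, keepdims=True)
        return (grad - self._y * dot) / self._norm


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray,
    labels: np.ndarray,
    sample_weight: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. logits."""
    B = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    eps = 1e-12
    nll = -np.log(p[np.arange(B), labels] + eps)
    w = np.ones(B) if sample_weight is None else np.asarray(sample_weight, float)
    wsum = w.sum()
    loss = float((w * nll).sum() / wsum)
    dlogits = p
    dlogits[np.arange(B), labels] -= 1.0
    dlogits *= (w / wsum)[:, None]
    return loss, dlogits.astype(DTYPE)


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params: list[Param], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data, dtype=np.float64) for p in params]
        self.v = [np.zeros_like(p.data, dtype=np.float64) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad.astype(np.float64)
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= (self.lr * (m / bc1) /
                       (np.sqrt(v / bc2) + self.eps)).astype(DTYPE)
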