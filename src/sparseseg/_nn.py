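"""Minimal NumPy building blocks for small 3D convolutional networks.

Everything here operates on channels-last arrays shaped ``(N, D, H, W, C)``
and supports a hand-written backward pass, which is all the patch-scale
networks in this package need.  Convolutions are "valid" (no padding) with
unit stride, the only mode the dual-pathway architecture uses; they are
evaluated as an accumulation of one small BLAS matmul per kernel offset,
which avoids im2col copies and on 1 CPU trains the tiny presets in minutes.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv3d",
    "ReLU",
    "Adam",
    "mean_pool3d",
    "mean_pool3d_backward",
    "upsample_nearest3d",
    "upsample_nearest3d_backward",
    "softmax",
    "soft_dice_loss",
]


class Conv3d:
    """Valid 3D convolution (cross-correlation) with bias, channels-last.

    Weights are He-initialized from ``rng`` and stored as
    ``(k, k, k, c_in, c_out)``.  ``kernel=1`` degenerates to a per-voxel
    dense layer, which is how the "fully connected" layers of the network
    are realized.  ``needs_input_grad=False`` skips the input-gradient
    computation (used for the first layer of a pathway).
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 dtype=np.float32, needs_input_grad: bool = True):
        fan_in = c_in * kernel**3
        scale = np.sqrt(2.0 / fan_in)
        self.w = (rng.standard_normal((kernel, kernel, kernel, c_in, c_out))
                  * scale).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.c_in, self.c_out, self.k = c_in, c_out, kernel
        self.needs_input_grad = needs_input_grad
        self._x = None
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    @property
    def n_params(self) -> int:
        return self.w.size + self.b.size

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        k = self.k
        if k == 1:
            return x @ self.w[0, 0, 0] + self.b
        n, d, h, w_ax, _ = x.shape
        do, ho, wo = d - k + 1, h - k + 1, w_ax - k + 1
        y = np.empty((n, do, ho, wo, self.c_out), dtype=x.dtype)
        y[:] = self.b
        for i in range(k):
            for j in range(k):
                for l in range(k):
                    y += x[:, i:i + do, j:j + ho, l:l + wo, :] @ self.w[i, j, l]
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray | None:
        x, k = self._x, self.k
        self.db = dy.reshape(-1, self.c_out).sum(axis=0)
        if k == 1:
            x2 = x.reshape(-1, self.c_in)
            dy2 = dy.reshape(-1, self.c_out)
            self.dw = (x2.T @ dy2).reshape(self.w.shape)
            if not self.needs_input_grad:
                return None
            return (dy2 @ self.w[0, 0, 0].T).reshape(x.shape)
        do, ho, wo = dy.shape[1:4]
        dy2 = np.ascontiguousarray(dy).reshape(-1, self.c_out)
        self.dw = np.empty_like(self.w)
        dx = np.zeros_like(x) if self.needs_input_grad else None
        for i in range(k):
            for j in range(k):
                for l in range(k):
                    xs = x[:, i:i + do, j:j + ho, l:l + wo, :]
                    cols = np.ascontiguousarray(xs).reshape(-1, self.c_in)
                    self.dw[i, j, l] = cols.T @ dy2
                    if dx is not None:
                        dx[:, i:i + do, j:j + ho, l:l + wo, :] += dy @ self.w[i, j, l].T
        return dx

    def params_and_grads(self):
        yield self.w, self.dw
        yield self.b, self.db


class ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


def mean_pool3d(x: np.ndarray, f: int) -> np.ndarray:
    """Non-overlapping mean pooling by factor ``f`` on each spatial axis."""
    n, d, h, w, c = x.shape
    if d % f or h % f or w % f:
        raise ValueError(f"spatial size {(d, h, w)} not divisible by {f}")
    xr = x.reshape(n, d // f, f, h // f, f, w // f, f, c)
    return xr.mean(axis=(2, 4, 6))


def mean_pool3d_backward(dy: np.ndarray, f: int) -> np.ndarray:
    g = dy / f**3
    return np.repeat(np.repeat(np.repeat(g, f, axis=1), f, axis=2), f, axis=3)


def upsample_nearest3d(x: np.ndarray, f: int) -> np.ndarray:
    return np.repeat(np.repeat(np.repeat(x, f, axis=1), f, axis=2), f, axis=3)


def upsample_nearest3d_backward(dy: np.ndarray, f: int) -> np.ndarray:
    n, d, h, w, c = dy.shape
    return dy.reshape(n, d // f, f, h // f, f, w // f, f, c).sum(axis=(2, 4, 6))


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    zmax = z.max(axis=axis, keepdims=True)
    e = np.exp(z - zmax)
    return e / e.sum(axis=axis, keepdims=True)


def soft_dice_loss(probs: np.ndarray, labels: np.ndarray, eps: float = 1e-5):
    """Batch-averaged soft Dice loss on the foreground class.

    probs:  (N, d, h, w, 2) class probabilities (channel 1 = foreground)
    labels: (N, d, h, w) binary ground truth

    Returns ``(loss, dprobs)`` where ``dprobs`` is the gradient with respect
    to the full probability tensor (background channel gradient is zero).
    """
    p = probs[..., 1]
    y = labels.astype(p.dtype)
    ax = (1, 2, 3)
    inter = (p * y).sum(axis=ax)
    denom = p.sum(axis=ax) + y.sum(axis=ax) + eps
    dice = (2.0 * inter + eps) / denom
    loss = float(np.mean(1.0 - dice))
    n = p.shape[0]
    # d(1-dice_i)/dp = -(2*y*denom - (2*inter+eps)) / denom^2, averaged over batch
    bcast = (slice(None), None, None, None)
    dp = -(2.0 * y * denom[bcast] - (2.0 * inter + eps)[bcast]) / (denom**2)[bcast]
    dprobs = np.zeros_like(probs)
    dprobs[..., 1] = dp / n
    return loss, dprobs


class Adam:
    """Adam optimizer over a list of ``(param, grad)`` producing layers."""

    def __init__(self, layers, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.layers = [l for l in layers if hasattr(l, "params_and_grads")]
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for l in self.layers for p, _ in l.params_and_grads()]
        self.v = [np.zeros_like(p) for l in self.layers for p, _ in l.params_and_grads()]

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        i = 0
        for layer in self.layers:
            for p, g in layer.params_and_grads():
                m, v = self.m[i], self.v[i]
                m *= b1
                m += (1 - b1) * g
                v *= b2
                v += (1 - b2) * g * g
                p -= lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
                i += 1
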