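"""A compact NumPy neural-network engine with hand-derived backpropagation.

Implements exactly the layers the segmentation backbone needs — 3x3x3 and
1x1x1 convolutions, group normalization, ReLU, 2x average-pooling, nearest-
neighbour upsampling and channel concatenation — each as a stateless
``forward(x) -> (y, cache)`` / ``backward(gy, cache) -> gx`` pair that
accumulates parameter gradients on the layer.  Activations are channels-first
``(C, D, H, W)`` single samples; mini-batches are looped by the caller.

Backprop through the full stack also yields the gradient of the loss with
respect to the *input image*, which the adversarial module needs.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Layer:
    """Base class: layers with parameters override ``params``."""

    def params(self) -> list[tuple[str, np.ndarray, np.ndarray]]:
        """(name, value, grad) triples; grads are accumulated in place."""
        return []

    def forward(self, x: np.ndarray, need_cache: bool = True):
        raise NotImplementedError

    def backward(self, gy: np.ndarray, cache) -> np.ndarray:
        raise NotImplementedError


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(C, D, H, W) -> (k^3 * C, D*H*W) patch matrix for stride-1 convolution.

    Row ``t*C + c`` holds channel ``c`` shifted by kernel offset ``t``; built
    with one contiguous block copy per offset, which is far cheaper than a
    fancy-strided gather.
    """
    c, d, h, w = x.shape
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (pad, pad)))
    col = np.empty((k ** 3, c, d, h, w), dtype=x.dtype)
    t = 0
    for dz in range(k):
        for dy in range(k):
            for dx in range(k):
                col[t] = xp[:, dz:dz + d, dy:dy + h, dx:dx + w]
                t += 1
    return col.reshape(k ** 3 * c, d * h * w)


def _w_matrix(w: np.ndarray) -> np.ndarray:
    """(out, in, k, k, k) kernel -> (out, k^3 * in) matrix matching _im2col."""
    out_ch, in_ch = w.shape[:2]
    return w.transpose(0, 2, 3, 4, 1).reshape(out_ch, -1)


class Conv3d(Layer):
    """Same-padded stride-1 3D convolution (kernel 3 or 1)."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator, k: int = 3):
        if k not in (1, 3):
            raise ValueError("kernel must be 1 or 3")
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, k
        fan_in = in_ch * k ** 3
        scale = np.sqrt(2.0 / fan_in)  # He initialization for ReLU stacks
        self.w = (rng.standard_normal((out_ch, in_ch, k, k, k)) * scale).astype(DTYPE)
        self.b = np.zeros(out_ch, dtype=DTYPE)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    def params(self):
        return [("w", self.w, self.gw), ("b", self.b, self.gb)]

    def forward(self, x: np.ndarray, need_cache: bool = True):
        c, d, h, wdt = x.shape
        if self.k == 1:
            wm = self.w.reshape(self.out_ch, self.in_ch)
            y = (wm @ x.reshape(c, -1) + self.b[:, None]).reshape(self.out_ch, d, h, wdt)
            return y.astype(DTYPE, copy=False), (x if need_cache else None)
        col = _im2col(x, self.k, pad=1)
        wm = _w_matrix(self.w)
        y = (wm @ col + self.b[:, None]).reshape(self.out_ch, d, h, wdt)
        return y.astype(DTYPE, copy=False), ((col, x.shape) if need_cache else None)

    def backward(self, gy: np.ndarray, cache) -> np.ndarray:
        gy_flat = gy.reshape(self.out_ch, -1)
        if self.k == 1:
            x = cache
            self.gw += (gy_flat @ x.reshape(self.in_ch, -1).T).reshape(self.w.shape)
            self.gb += gy_flat.sum(axis=1)
            wm = self.w.reshape(self.out_ch, self.in_ch)
            return (wm.T @ gy_flat).reshape((self.in_ch,) + gy.shape[1:]).astype(DTYPE)
        col, x_shape = cache
        k3 = self.k ** 3
        gw_mat = gy_flat @ col.T  # (out, k^3 * in), offset-major like _im2col
        self.gw += gw_mat.reshape(self.out_ch, self.k, self.k, self.k,
                                  self.in_ch).transpose(0, 4, 1, 2, 3)
        self.gb += gy_flat.sum(axis=1)
        # gx = full correlation of gy with the spatially flipped, transposed kernel
        wf = _w_matrix(
            self.w[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4))
        gcol = _im2col(gy, self.k, pad=1)
        return (wf @ gcol).reshape(x_shape).astype(DTYPE)


class GroupNorm(Layer):
    """Group normalization over (channel-group, D, H, W) with affine scale/shift."""

    def __init__(self, channels: int, groups: int | None = None, eps: float = 1e-5):
        if groups is None:
            groups = min(8, channels)
            while channels % groups:
                groups -= 1
        if channels % groups:
            raise ValueError("groups must divide channels")
        self.c, self.g, self.eps = channels, groups, eps
        self.gamma = np.ones(channels, dtype=DTYPE)
        self.beta = np.zeros(channels, dtype=DTYPE)
        self.ggamma = np.zeros_like(self.gamma)
        self.gbeta = np.zeros_like(self.beta)

    def params(self):
        return [("gamma", self.gamma, self.ggamma), ("beta", self.beta, self.gbeta)]

    def forward(self, x: np.ndarray, need_cache: bool = True):
        c, d, h, w = x.shape
        xg = x.reshape(self.g, -1)
        mu = xg.mean(axis=1, keepdims=True)
        var = xg.var(axis=1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = ((xg - mu) * inv).reshape(x.shape)
        y = xhat * self.gamma[:, None, None, None] + self.beta[:, None, None, None]
        return y.astype(DTYPE, copy=False), ((xhat, inv) if need_cache else None)

    def backward(self, gy: np.ndarray, cache) -> np.ndarray:
        xhat, inv = cache
        self.ggamma += (gy * xhat).sum(axis=(1, 2, 3))
        self.gbeta += gy.sum(axis=(1, 2, 3))
        gxhat = gy * self.gamma[:, None, None, None]
        gg = gxhat.reshape(self.g, -1)
        xh = xhat.reshape(self.g, -1)
        m = gg.shape[1]
        gx = inv * (gg - gg.mean(axis=1, keepdims=True)
                    - xh * (gg * xh).mean(axis=1, keepdims=True))
        return gx.reshape(gy.shape).astype(DTYPE)


class ReLU(Layer):
    def forward(self, x: np.ndarray, need_cache: bool = True):
        y = np.maximum(x, 0)
        return y, ((x > 0) if need_cache else None)

    def backward(self, gy: np.ndarray, cache) -> np.ndarray:
        return (gy * cache).astype(DTYPE)


class AvgPool3d(Layer):
    """2x2x2 average pooling; spatial dims must be even."""

    def forward(self, x: np.ndarray, need_cache: bool = True):
        c, d, h, w = x.shape
        if d % 2 or h % 2 or w % 2:
            raise ValueError(f"odd spatial dims {x.shape[1:]} cannot be pooled")
        y = x.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2).mean(axis=(2, 4, 6))
        return y.astype(DTYPE, copy=False), None

    def backward(self, gy: np.ndarray, cache) -> np.ndarray:
        g = gy / 8.0
        for ax in (1, 2, 3):
            g = np.repeat(g, 2, axis=ax)
        return g.astype(DTYPE)


class UpsampleNearest(Layer):
    """Nearest-neighbour 2x upsampling in all three spatial dims."""

    def forward(self, x: np.ndarray, need_cache: bool = True):
        y = x
        for ax in (1, 2, 3):
            y = np.repeat(y, 2, axis=ax)
        return y.astype(DTYPE, copy=False), None

    def backward(self, gy: np.ndarray, cache) -> np.ndarray:
        c, d, h, w = gy.shape
        return gy.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2).sum(
            axis=(2, 4, 6)).astype(DTYPE)


def softmax_channels(z: np.ndarray) -> np.ndarray:
    """Channel-axis (axis 0) softmax of a (C, D, H, W) logit map."""
    z = z - z.max(axis=0, keepdims=True)
    e = np.exp(z)
    return (e / e.sum(axis=0, keepdims=True)).astype(DTYPE)


def softmax_backward(p: np.ndarray, gp: np.ndarray) -> np.ndarray:
    """Map a gradient w.r.t. probabilities to a gradient w.r.t. logits."""
    dot = (p * gp).sum(axis=0, keepdims=True)
    return (p * (gp - dot)).astype(DTYPE)


class Adam:
    """Adam with (coupled) L2 weight decay added to the gradient."""

    def __init__(self, params: list[tuple[str, np.ndarray, np.ndarray]],
                 lr: float = 2e-4, betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 5e-4):
        self.params = params
        self.lr, self.eps, self.weight_decay = lr, eps, weight_decay
        self.b1, self.b2 = betas
        self.t = 0
        self.m = [np.zeros_like(p) for _, p, _ in params]
        self.v = [np.zeros_like(p) for _, p, _ in params]

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for i, (_, p, g) in enumerate(self.params):
            grad = g + self.weight_decay * p
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * grad * grad
            p -= (self.lr * (self.m[i] / bc1)
                  / (np.sqrt(self.v[i] / bc2) + self.eps)).astype(p.dtype)

    def zero_grad(self) -> None:
        for _, _, g in self.params:
            g[...] = 0.0
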