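"""Minimal CPU neural-network layers with explicit backprop.

Just enough machinery for the U-shaped segmentation model: im2col-based
2-D convolutions (full and depthwise), batch normalization,
squeeze-and-excitation gating, 2x2 stride-2 transposed convolution,
ReLU, a softmax cross-entropy head and an Adam optimizer.  Tensors are
``(N, C, H, W)`` float64 arrays; every layer caches what it needs on
``forward`` and returns input gradients from ``backward``.
"""

from __future__ import annotations

import numpy as np


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)


class Module:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


# ---------------------------------------------------------------------------
# im2col plumbing
# ---------------------------------------------------------------------------

def _im2col(x, k, stride, pad):
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]              # (n, c, ho, wo, k, k)
    col = win.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * k * k, ho * wo)
    return np.ascontiguousarray(col), ho, wo


def _col2im(dcol, xshape, k, stride, pad):
    n, c, h, w = xshape
    hp, wp = h + 2 * pad, w + 2 * pad
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    dxp = np.zeros((n, c, hp, wp))
    d = dcol.reshape(n, c, k, k, ho, wo)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += d[:, :, i, j]
    if pad:
        return dxp[:, :, pad:hp - pad, pad:wp - pad]
    return dxp


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Conv2d(Module):
    """Same-padded 2-D convolution (He-initialized)."""

    def __init__(self, cin, cout, k, stride=1, rng=None, bias=True):
        rng = rng or np.random.default_rng()
        std = np.sqrt(2.0 / (cin * k * k))
        self.w = Param(rng.normal(0.0, std, size=(cout, cin * k * k)))
        self.b = Param(np.zeros(cout)) if bias else None
        self.k, self.stride, self.pad = k, stride, k // 2
        self.cin, self.cout = cin, cout

    def params(self):
        return [self.w] + ([self.b] if self.b is not None else [])

    def forward(self, x, train=True):
        self._xshape = x.shape
        col, ho, wo = _im2col(x, self.k, self.stride, self.pad)
        self._col = col
        y = np.einsum("of,nfl->nol", self.w.value, col)
        if self.b is not None:
            y += self.b.value[:, None]
        return y.reshape(x.shape[0], self.cout, ho, wo)

    def backward(self, dy):
        n = dy.shape[0]
        dyf = dy.reshape(n, self.cout, -1)
        self.w.grad += np.einsum("nol,nfl->of", dyf, self._col)
        if self.b is not None:
            self.b.grad += dyf.sum(axis=(0, 2))
        dcol = np.einsum("of,nol->nfl", self.w.value, dyf)
        return _col2im(dcol, self._xshape, self.k, self.stride, self.pad)


class DepthwiseConv2d(Module):
    """Per-channel (depthwise) convolution."""

    def __init__(self, c, k, stride=1, rng=None):
        rng = rng or np.random.default_rng()
        std = np.sqrt(2.0 / (k * k))
        self.w = Param(rng.normal(0.0, std, size=(c, k * k)))
        self.b = Param(np.zeros(c))
        self.c, self.k, self.stride, self.pad = c, k, stride, k // 2

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=True):
        self._xshape = x.shape
        col, ho, wo = _im2col(x, self.k, self.stride, self.pad)
        n = x.shape[0]
        colc = col.reshape(n, self.c, self.k * self.k, -1)
        self._colc = colc
        y = np.einsum("cf,ncfl->ncl", self.w.value, colc) + self.b.value[:, None]
        return y.reshape(n, self.c, ho, wo)

    def backward(self, dy):
        n = dy.shape[0]
        dyf = dy.reshape(n, self.c, -1)
        self.w.grad += np.einsum("ncl,ncfl->cf", dyf, self._colc)
        self.b.grad += dyf.sum(axis=(0, 2))
        dcolc = np.einsum("cf,ncl->ncfl", self.w.value, dyf)
        dcol = dcolc.reshape(n, self.c * self.k * self.k, -1)
        return _col2im(dcol, self._xshape, self.k, self.stride, self.pad)


class BatchNorm2d(Module):
    def __init__(self, c, momentum=0.9, eps=1e-5):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.momentum, self.eps = momentum, eps
        self.run_mean = np.zeros(c)
        self.run_var = np.ones(c)

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            # in place so external references (checkpointing) stay valid
            self.run_mean *= self.momentum
            self.run_mean += (1 - self.momentum) * mean
            self.run_var *= self.momentum
            self.run_var += (1 - self.momentum) * var
        else:
            mean, var = self.run_mean, self.run_var
        self._std = np.sqrt(var + self.eps)[None, :, None, None]
        self._xhat = (x - mean[None, :, None, None]) / self._std
        return self.gamma.value[None, :, None, None] * self._xhat \
            + self.beta.value[None, :, None, None]

    def backward(self, dy):
        axes = (0, 2, 3)
        self.gamma.grad += (dy * self._xhat).sum(axis=axes)
        self.beta.grad += dy.sum(axis=axes)
        g = self.gamma.value[None, :, None, None]
        dxhat = dy * g
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        mean_dxhat = dxhat.mean(axis=axes, keepdims=True)
        mean_dxhat_xhat = (dxhat * self._xhat).mean(axis=axes, keepdims=True)
        return (dxhat - mean_dxhat - self._xhat * mean_dxhat_xhat) / self._std


class ReLU(Module):
    def forward(self, x, train=True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class SEBlock(Module):
    """Squeeze-and-excitation: global-pool -> bottleneck MLP -> sigmoid gate."""

    def __init__(self, c, reduction=4, rng=None):
        rng = rng or np.random.default_rng()
        cr = max(c // reduction, 1)
        self.w1 = Param(rng.normal(0.0, np.sqrt(2.0 / c), size=(cr, c)))
        self.b1 = Param(np.zeros(cr))
        self.w2 = Param(rng.normal(0.0, np.sqrt(2.0 / cr), size=(c, cr)))
        self.b2 = Param(np.zeros(c))

    def params(self):
        return [self.w1, self.b1, self.w2, self.b2]

    def forward(self, x, train=True):
        self._x = x
        self._s = x.mean(axis=(2, 3))                       # (n, c)
        self._h = self._s @ self.w1.value.T + self.b1.value
        self._hr = np.maximum(self._h, 0.0)
        z = self._hr @ self.w2.value.T + self.b2.value
        self._g = 1.0 / (1.0 + np.exp(-z))                  # (n, c)
        return x * self._g[:, :, None, None]

    def backward(self, dy):
        dx = dy * self._g[:, :, None, None]
        dg = (dy * self._x).sum(axis=(2, 3))
        dz = dg * self._g * (1.0 - self._g)
        self.w2.grad += dz.T @ self._hr
        self.b2.grad += dz.sum(axis=0)
        dhr = dz @ self.w2.value
        dh = dhr * (self._h > 0)
        self.w1.grad += dh.T @ self._s
        self.b1.grad += dh.sum(axis=0)
        ds = dh @ self.w1.value                             # (n, c)
        hw = self._x.shape[2] * self._x.shape[3]
        dx += ds[:, :, None, None] / hw
        return dx


class ConvTranspose2x2(Module):
    """2x2 transposed convolution with stride 2 (exact x2 upsampling)."""

    def __init__(self, cin, cout, rng=None):
        rng = rng or np.random.default_rng()
        std = np.sqrt(2.0 / cin)
        self.w = Param(rng.normal(0.0, std, size=(2, 2, cout, cin)))
        self.b = Param(np.zeros(cout))
        self.cin, self.cout = cin, cout

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=True):
        self._x = x
        n, c, h, w = x.shape
        y = np.empty((n, self.cout, 2 * h, 2 * w))
        for i in range(2):
            for j in range(2):
                y[:, :, i::2, j::2] = np.einsum("oc,nchw->nohw", self.w.value[i, j], x)
        return y + self.b.value[None, :, None, None]

    def backward(self, dy):
        dx = np.zeros_like(self._x)
        for i in range(2):
            for j in range(2):
                dy_ij = dy[:, :, i::2, j::2]
                self.w.grad[i, j] += np.einsum("nohw,nchw->oc", dy_ij, self._x)
                dx += np.einsum("oc,nohw->nchw", self.w.value[i, j], dy_ij)
        self.b.grad += dy.sum(axis=(0, 2, 3))
        return dx


# ---------------------------------------------------------------------------
# loss and optimization
# ---------------------------------------------------------------------------

def softmax(logits: np.ndarray) -> np.ndarray:
    """Channel-wise softmax of (n, k, h, w) logits."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean per-pixel cross-entropy and its gradient w.r.t. logits."""
    p = softmax(logits)
    n, k, h, w = logits.shape
    idx_n, idx_h, idx_w = np.ogrid[:n, :h, :w]
    picked = p[idx_n, labels, idx_h, idx_w]
    loss = float(-np.log(np.maximum(picked, 1e-12)).mean())
    onehot = np.zeros_like(p)
    onehot[idx_n, labels, idx_h, idx_w] = 1.0
    dlogits = (p - onehot) / (n * h * w)
    return loss, dlogits


class Adam:
    def __init__(self, params: list[Param], lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * p.grad
            v[...] = self.b2 * v + (1 - self.b2) * p.grad**2
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
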