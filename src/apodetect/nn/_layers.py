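"""NumPy neural-network layers with explicit forward/backward passes.

Each layer stores its parameters in ``params`` and accumulates gradients
into ``grads`` during ``backward``.  Convolutions use im2col with a
shared-weight matmul; the col2im scatter in the backward pass loops over
the k*k kernel offsets only.  All arrays share the dtype of the layer's
parameters (float32 in production, float64 for gradient checking).
"""

from __future__ import annotations

from typing import Dict, Optional

import numpy as np


class Layer:
    def __init__(self):
        self.params: Dict[str, np.ndarray] = {}
        self.grads: Dict[str, np.ndarray] = {}

    def forward(self, x, train: bool):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - interface
        raise NotImplementedError


class Conv2d(Layer):
    """kxk same-padding convolution, stride 1, channels-last (N, H, W, C).

    The im2col buffer is assembled from k*k contiguous slice copies and
    consumed by a single matmul, which keeps memory traffic sequential.
    ``needs_input_grad=False`` (first layer) skips the col2im scatter.
    """

    def __init__(self, c_in: int, c_out: int, k: int = 3, rng=None,
                 dtype=np.float32, needs_input_grad: bool = True):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * k * k
        self.k = k
        self.c_in, self.c_out = c_in, c_out
        self.needs_input_grad = needs_input_grad
        self.params["W"] = (rng.normal(0, np.sqrt(2.0 / fan_in), (fan_in, c_out))
                            .astype(dtype))
        self.params["b"] = np.zeros(c_out, dtype=dtype)

    def forward(self, x, train: bool):
        N, H, W, C = x.shape
        k, p = self.k, self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        cols = np.empty((N, H, W, k * k * C), dtype=x.dtype)
        for idx in range(k * k):
            i, j = divmod(idx, k)
            cols[..., idx * C:(idx + 1) * C] = xp[:, i:i + H, j:j + W, :]
        self._cols = cols.reshape(N * H * W, k * k * C)
        self._xshape = x.shape
        y = self._cols @ self.params["W"] + self.params["b"]
        return y.reshape(N, H, W, self.c_out)

    def backward(self, dy):
        N, H, W, C = self._xshape
        k, p = self.k, self.k // 2
        dy2 = dy.reshape(-1, self.c_out)
        self.grads["W"] = self._cols.T @ dy2
        self.grads["b"] = dy2.sum(axis=0)
        self._cols = None
        if not self.needs_input_grad:
            return None
        dcols = (dy2 @ self.params["W"].T).reshape(N, H, W, k * k * C)
        dxp = np.zeros((N, H + 2 * p, W + 2 * p, C), dtype=dy.dtype)
        for idx in range(k * k):
            i, j = divmod(idx, k)
            dxp[:, i:i + H, j:j + W, :] += dcols[..., idx * C:(idx + 1) * C]
        return dxp[:, p:p + H, p:p + W, :]


class ReLU(Layer):
    def forward(self, x, train: bool):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class BatchNorm2d(Layer):
    """Per-channel batch normalization over (N, H, W), channels-last."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5, dtype=np.float32):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params["gamma"] = np.ones(c, dtype=dtype)
        self.params["beta"] = np.zeros(c, dtype=dtype)
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)

    def forward(self, x, train: bool):
        if train:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean).astype(x.dtype)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var).astype(x.dtype)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = (1.0 / np.sqrt(var + self.eps)).astype(x.dtype)
        xhat = (x - mean) * invstd
        if train:
            self._xhat, self._invstd = xhat, invstd
        return xhat * self.params["gamma"] + self.params["beta"]

    def backward(self, dy):
        xhat, invstd = self._xhat, self._invstd
        n = dy.shape[0] * dy.shape[1] * dy.shape[2]
        self.grads["gamma"] = (dy * xhat).sum(axis=(0, 1, 2))
        self.grads["beta"] = dy.sum(axis=(0, 1, 2))
        dxhat = dy * self.params["gamma"]
        sum_dxhat = dxhat.sum(axis=(0, 1, 2))
        sum_dxhat_xhat = (dxhat * xhat).sum(axis=(0, 1, 2))
        dx = (invstd / n) * (n * dxhat - sum_dxhat - xhat * sum_dxhat_xhat)
        self._xhat = None
        return dx


class Dropout(Layer):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, p: float, rng: Optional[np.random.Generator] = None):
        super().__init__()
        if not 0 <= p < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p = p
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x, train: bool):
        if not train or self.p == 0:
            self._mask = None
            return x
        u = self.rng.random(x.shape, dtype=np.float32)
        self._mask = (u >= self.p).astype(x.dtype) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask


class MaxPool2d(Layer):
    """2x2 max pooling, stride 2, floor division of odd sizes, channels-last."""

    def forward(self, x, train: bool):
        N, H, W, C = x.shape
        Ho, Wo = H // 2, W // 2
        xc = x[:, :Ho * 2, :Wo * 2, :]
        a = xc.reshape(N, Ho, 2, Wo, 2, C)
        m01 = np.maximum(a[:, :, 0, :, 0], a[:, :, 0, :, 1])
        m23 = np.maximum(a[:, :, 1, :, 0], a[:, :, 1, :, 1])
        y = np.maximum(m01, m23)
        if train:
            self._x = x
            self._y = y
        return y

    def backward(self, dy):
        x, y = self._x, self._y
        N, H, W, C = x.shape
        Ho, Wo = H // 2, W // 2
        dx = np.zeros_like(x)
        dv = dy.copy()  # route each output grad to the first maximal input
        for i in range(2):
            for j in range(2):
                win = x[:, i:Ho * 2:2, j:Wo * 2:2, :]
                hit = (win == y) & (dv != 0)
                dx[:, i:Ho * 2:2, j:Wo * 2:2, :] += np.where(hit, dv, 0)
                dv = np.where(hit, 0, dv)
        self._x = self._y = None
        return dx


class Linear(Layer):
    def __init__(self, d_in: int, d_out: int, rng=None, scale: Optional[float] = None,
                 dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        if scale is None:
            scale = np.sqrt(2.0 / d_in)
        self.params["W"] = rng.normal(0, scale, (d_out, d_in)).astype(dtype)
        self.params["b"] = np.zeros(d_out, dtype=dtype)

    def forward(self, x, train: bool):
        self._xshape = x.shape
        x2 = x.reshape(-1, x.shape[-1])
        self._x2 = x2
        y = x2 @ self.params["W"].T + self.params["b"]
        return y.reshape(x.shape[:-1] + (self.params["b"].shape[0],))

    def backward(self, dy):
        dy2 = dy.reshape(-1, dy.shape[-1])
        self.grads["W"] = dy2.T @ self._x2
        self.grads["b"] = dy2.sum(axis=0)
        dx = dy2 @ self.params["W"]
        self._x2 = None
        return dx.reshape(self._xshape)


class LayerNorm(Layer):
    def __init__(self, d: int, eps: float = 1e-5, dtype=np.float32):
        super().__init__()
        self.eps = eps
        self.params["gamma"] = np.ones(d, dtype=dtype)
        self.params["beta"] = np.zeros(d, dtype=dtype)

    def forward(self, x, train: bool):
        mean = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        self._invstd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean) * self._invstd
        return self._xhat * self.params["gamma"] + self.params["beta"]

    def backward(self, dy):
        xhat, invstd = self._xhat, self._invstd
        d = dy.shape[-1]
        self.grads["gamma"] = (dy * xhat).reshape(-1, d).sum(axis=0)
        self.grads["beta"] = dy.reshape(-1, d).sum(axis=0)
        dxhat = dy * self.params["gamma"]
        dx = invstd * (
            dxhat
            - dxhat.mean(axis=-1, keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True)
        )
        self._xhat = None
        return dx


def _softmax_lastaxis(z):
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class MultiHeadSelfAttention(Layer):
    """Standard scaled dot-product self-attention over K tokens."""

    def __init__(self, d: int, n_heads: int, rng=None, dtype=np.float32):
        super().__init__()
        if d % n_heads != 0:
            raise ValueError(f"token_dim {d} not divisible by n_heads {n_heads}")
        rng = rng or np.random.default_rng(0)
        self.d, self.h = d, n_heads
        self.dh = d // n_heads
        scale = np.sqrt(1.0 / d)
        self.params["Wqkv"] = rng.normal(0, scale, (3 * d, d)).astype(dtype)
        self.params["bqkv"] = np.zeros(3 * d, dtype=dtype)
        self.params["Wo"] = rng.normal(0, scale, (d, d)).astype(dtype)
        self.params["bo"] = np.zeros(d, dtype=dtype)

    def _split(self, x):
        N, K, _ = x.shape
        return x.reshape(N, K, self.h, self.dh).transpose(0, 2, 1, 3)

    def forward(self, x, train: bool):
        N, K, d = x.shape
        self._x = x
        qkv = x @ self.params["Wqkv"].T + self.params["bqkv"]
        q, k, v = np.split(qkv, 3, axis=-1)
        qh, kh, vh = self._split(q), self._split(k), self._split(v)  # (N,h,K,dh)
        scores = qh @ kh.transpose(0, 1, 3, 2) / np.sqrt(self.dh)
        att = _softmax_lastaxis(scores)
        ctx = att @ vh  # (N,h,K,dh)
        self._cache = (qh, kh, vh, att)
        merged = ctx.transpose(0, 2, 1, 3).reshape(N, K, d)
        self._merged = merged
        return merged @ self.params["Wo"].T + self.params["bo"]

    def backward(self, dy):
        N, K, d = self._x.shape
        qh, kh, vh, att = self._cache
        dy2 = dy.reshape(-1, d)
        self.grads["Wo"] = dy2.T @ self._merged.reshape(-1, d)
        self.grads["bo"] = dy2.sum(axis=0)
        dmerged = (dy2 @ self.params["Wo"]).reshape(N, K, d)
        dctx = dmerged.reshape(N, K, self.h, self.dh).transpose(0, 2, 1, 3)
        datt = dctx @ vh.transpose(0, 1, 3, 2)
        dvh = att.transpose(0, 1, 3, 2) @ dctx
        dscores = att * (datt - (datt * att).sum(axis=-1, keepdims=True))
        dscores /= np.sqrt(self.dh)
        dqh = dscores @ kh
        dkh = dscores.transpose(0, 1, 3, 2) @ qh

        def _merge(a):
            return a.transpose(0, 2, 1, 3).reshape(N, K, d)

        dqkv = np.concatenate([_merge(dqh), _merge(dkh), _merge(dvh)], axis=-1)
        dqkv2 = dqkv.reshape(-1, 3 * d)
        self.grads["Wqkv"] = dqkv2.T @ self._x.reshape(-1, d)
        self.grads["bqkv"] = dqkv2.sum(axis=0)
        dx = (dqkv2 @ self.params["Wqkv"]).reshape(N, K, d)
        self._x = self._cache = self._merged = None
        return dx
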