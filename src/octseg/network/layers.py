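"""Minimal numpy neural-network layers with hand-derived backprop.

Only what the encoder-decoder segmentation network needs: same-padded 2-D
convolution, batch normalization, ReLU, 2x2 max-pooling that records argmax
indices, and the matching index-based unpooling.  Each layer instance caches
its forward activations and is used once per forward pass, so ``backward``
can be called in reverse graph order without an autograd engine.

Array layout is (batch, channels, rows, cols) throughout.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Conv2d:
    """Same-padded convolution (cross-correlation) with bias."""

    def __init__(self, in_channels: int, out_channels: int,
                 kernel: tuple[int, int], rng: np.random.Generator):
        kh, kw = kernel
        if kh % 2 == 0 or kw % 2 == 0:
            raise ValueError("kernel dims must be odd for same padding")
        fan_in = in_channels * kh * kw
        # He/fan-in scaled init, suited to the ReLU nonlinearity
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(out_channels, in_channels, kh, kw))
        self.b = np.zeros(out_channels)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache = None

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.dW, self.db]

    def forward(self, x: np.ndarray) -> np.ndarray:
        F, C, kh, kw = self.W.shape
        ph, pw = kh // 2, kw // 2
        B, _, H, Wd = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
        # (B, C, H, Wd, kh, kw) view -> (B*H*Wd, C*kh*kw)
        win = sliding_window_view(xp, (kh, kw), axis=(2, 3))
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(B * H * Wd, C * kh * kw)
        out = cols @ self.W.reshape(F, -1).T + self.b
        self._cache = (cols, x.shape)
        return out.reshape(B, H, Wd, F).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, xshape = self._cache
        F, C, kh, kw = self.W.shape
        B, _, H, Wd = xshape
        dmat = dout.transpose(0, 2, 3, 1).reshape(-1, F)
        self.dW[...] = (dmat.T @ cols).reshape(self.W.shape)
        self.db[...] = dmat.sum(axis=0)
        dcols = (dmat @ self.W.reshape(F, -1)).reshape(B, H, Wd, C, kh, kw)
        ph, pw = kh // 2, kw // 2
        dxp = np.zeros((B, C, H + 2 * ph, Wd + 2 * pw))
        for i in range(kh):
            for j in range(kw):
                dxp[:, :, i:i + H, j:j + Wd] += dcols[:, :, :, :, i, j].transpose(
                    0, 3, 1, 2)
        self._cache = None
        return dxp[:, :, ph:ph + H, pw:pw + Wd]


class BatchNorm2d:
    """Per-channel batch normalization with running statistics for eval."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.dgamma = np.zeros(channels)
        self.dbeta = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    @property
    def params(self):
        return [self.gamma, self.beta]

    @property
    def grads(self):
        return [self.dgamma, self.dbeta]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        axes = (0, 2, 3)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var)
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) / std[None, :, None, None]
        if training:
            self._cache = (xhat, std)
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, std = self._cache
        axes = (0, 2, 3)
        self.dgamma[...] = (dout * xhat).sum(axis=axes)
        self.dbeta[...] = dout.sum(axis=axes)
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        g = self.gamma[None, :, None, None] / std[None, :, None, None]
        dx = g * (dout
                  - dout.mean(axis=axes, keepdims=True)
                  - xhat * (dout * xhat).mean(axis=axes, keepdims=True))
        self._cache = None
        return dx


class ReLU:
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        out = dout * self._mask
        self._mask = None
        return out


class MaxPool2x2:
    """2x2 stride-2 max pooling recording argmax indices for unpooling."""

    def __init__(self):
        self.indices = None
        self._inshape = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, H, Wd = x.shape
        if H % 2 or Wd % 2:
            raise ValueError("pooling input dims must be even")
        win = x.reshape(B, C, H // 2, 2, Wd // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = win.reshape(B, C, H // 2, Wd // 2, 4)
        self.indices = flat.argmax(axis=-1)
        self._inshape = x.shape
        return np.take_along_axis(flat, self.indices[..., None], axis=-1)[..., 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return unpool_with_indices(dout, self.indices, self._inshape)


def unpool_with_indices(x: np.ndarray, indices: np.ndarray,
                        out_shape: tuple[int, int, int, int]) -> np.ndarray:
    """Place each value at its recorded argmax position, zeros elsewhere."""
    B, C, H, Wd = out_shape
    flat = np.zeros((B, C, H // 2, Wd // 2, 4))
    np.put_along_axis(flat, indices[..., None], x[..., None], axis=-1)
    return flat.reshape(B, C, H // 2, Wd // 2, 2, 2).transpose(
        0, 1, 2, 4, 3, 5).reshape(B, C, H, Wd)


class MaxUnpool2x2:
    """Index-based unpooling doubling resolution, paired with an encoder pool."""

    def __init__(self):
        self._indices = None
        self._outshape = None

    def forward(self, x: np.ndarray, indices: np.ndarray) -> np.ndarray:
        B, C, h, w = x.shape
        self._indices = indices
        self._outshape = (B, C, 2 * h, 2 * w)
        return unpool_with_indices(x, indices, self._outshape)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, C, H, Wd = self._outshape
        flat = dout.reshape(B, C, H // 2, 2, Wd // 2, 2).transpose(
            0, 1, 2, 4, 3, 5).reshape(B, C, H // 2, Wd // 2, 4)
        return np.take_along_axis(flat, self._indices[..., None], axis=-1)[..., 0]


def softmax_channels(z: np.ndarray) -> np.ndarray:
    """Per-pixel softmax over the channel axis of (B, C, H, W) logits."""
    zmax = z.max(axis=1, keepdims=True)
    e = np.exp(z - zmax)
    return e / e.sum(axis=1, keepdims=True)


def softmax_backward(p: np.ndarray, dp: np.ndarray) -> np.ndarray:
    """dL/dlogits from dL/dprobs through the per-pixel softmax Jacobian."""
    return p * (dp - (dp * p).sum(axis=1, keepdims=True))


class SGDMomentum:
    """Classical momentum SGD: v <- mu*v - lr*g; w <- w + v."""

    def __init__(self, params: list[np.ndarray], momentum: float):
        self.params = params
        self.momentum = momentum
        self.velocity = [np.zeros_like(p) for p in params]

    def step(self, grads: list[np.ndarray], lr: float) -> None:
        for p, g, v in zip(self.params, grads, self.velocity):
            v *= self.momentum
            v -= lr * g
            p += v
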