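"""Minimal CNN building blocks with explicit forward/backward passes.

Everything runs in float32 on channels-last ``(N, H, W, C)`` arrays — with
channels innermost, the im2col gather needed by convolution reduces to nine
row-contiguous block copies and the following matrix product needs no
transposes, which is what makes a pure-numpy network fast enough to train.
Each layer caches what its backward pass needs during
``forward(..., train=True)``; parameters and their gradients live on the
layer as plain numpy arrays updated in place by the optimizers, so references
held by an optimizer stay valid.
"""

from __future__ import annotations

import numpy as np


class Conv2d:
    """k x k same-padding convolution (k in {1, 3}), stride 1, He-normal init.

    For ``k=3`` the kernel is a ``(9, C_in, C_out)`` stack indexed by kernel
    offset (row-major over the 3x3 window); the convolution is nine
    near-contiguous shifted copies of the input followed by nine GEMMs, the
    fastest formulation available to a BLAS-backed numpy.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        if kernel not in (1, 3):
            raise ValueError("only 1x1 and 3x3 kernels are supported")
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, kernel
        fan_in = in_ch * kernel * kernel
        shape = (in_ch, out_ch) if kernel == 1 else (9, in_ch, out_ch)
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), shape).astype(np.float32)
        self.b = np.zeros(out_ch, np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None

    @staticmethod
    def _shifted(x: np.ndarray) -> np.ndarray:
        """(N,H,W,C) -> (9, N*H*W, C): the input under each 3x3 offset."""
        n, h, w, c = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        buf = np.empty((9, n, h, w, c), np.float32)
        for idx in range(9):
            i, j = divmod(idx, 3)
            buf[idx] = xp[:, i : i + h, j : j + w, :]
        return buf.reshape(9, n * h * w, c)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, h, w, c = x.shape
        if self.k == 1:
            cols = x.reshape(n * h * w, c)
            out = cols @ self.W
        else:
            cols = self._shifted(x)
            out = cols[4] @ self.W[4]  # center tap first, then accumulate
            for idx in (0, 1, 2, 3, 5, 6, 7, 8):
                out += cols[idx] @ self.W[idx]
        out += self.b
        if train:
            self._cols = cols
        return out.reshape(n, h, w, self.out_ch)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, f = dout.shape
        dmat = dout.reshape(n * h * w, f)
        self.db[...] = dmat.sum(axis=0)
        if self.k == 1:
            self.dW[...] = self._cols.T @ dmat
            self._cols = None
            return (dmat @ self.W.T).reshape(n, h, w, self.in_ch)
        for idx in range(9):
            self.dW[idx] = self._cols[idx].T @ dmat
        self._cols = None
        # transposed convolution: same-pad conv of dout with the spatially
        # rotated (offset 8-idx), channel-transposed kernel
        dcols = self._shifted(dout)
        dx = dcols[4] @ self.W[4].T
        for idx in (0, 1, 2, 3, 5, 6, 7, 8):
            dx += dcols[idx] @ self.W[8 - idx].T
        return dx.reshape(n, h, w, self.in_ch)

    def param_items(self, prefix: str):
        yield f"{prefix}.W", self.W, self.dW
        yield f"{prefix}.b", self.b, self.db

    def state_items(self, prefix: str):
        yield f"{prefix}.W", self.W
        yield f"{prefix}.b", self.b


class BatchNorm2d:
    """Per-channel batch normalization with running statistics for inference."""

    def __init__(self, n_ch: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(n_ch, np.float32)
        self.beta = np.zeros(n_ch, np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(n_ch, np.float32)
        self.running_var = np.ones(n_ch, np.float32)
        self.momentum, self.eps = momentum, eps
        self._xhat: np.ndarray | None = None
        self._inv_std: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        xhat = (x - mean.astype(np.float32)) * inv_std
        if train:
            self._xhat, self._inv_std = xhat, inv_std
        return self.gamma * xhat + self.beta

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._xhat, self._inv_std
        m = dout.shape[0] * dout.shape[1] * dout.shape[2]
        self.dgamma[...] = (dout * xhat).sum(axis=(0, 1, 2))
        self.dbeta[...] = dout.sum(axis=(0, 1, 2))
        dx = (self.gamma * inv_std) * (
            dout - self.dbeta / m - xhat * (self.dgamma / m)
        )
        self._xhat = None
        return dx.astype(np.float32)

    def param_items(self, prefix: str):
        yield f"{prefix}.gamma", self.gamma, self.dgamma
        yield f"{prefix}.beta", self.beta, self.dbeta

    def state_items(self, prefix: str):
        yield f"{prefix}.gamma", self.gamma
        yield f"{prefix}.beta", self.beta
        yield f"{prefix}.running_mean", self.running_mean
        yield f"{prefix}.running_var", self.running_var


class ReLU:
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = dout * self._mask
        self._mask = None
        return dx


class MaxPool2:
    """2x2 max pooling, stride 2; spatial dims must be even.

    Gradient routes to the first of the four window positions attaining the
    maximum (scan order: top-left, top-right, bottom-left, bottom-right).
    """

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        a = x[:, 0::2, 0::2, :]
        b = x[:, 0::2, 1::2, :]
        c = x[:, 1::2, 0::2, :]
        d = x[:, 1::2, 1::2, :]
        out = np.maximum(np.maximum(a, b), np.maximum(c, d))
        if train:
            ma = a == out
            mb = (b == out) & ~ma
            mc = (c == out) & ~(ma | mb)
            md = ~(ma | mb | mc)
            self._masks, self._in_shape = (ma, mb, mc, md), x.shape
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        ma, mb, mc, md = self._masks
        dx = np.zeros(self._in_shape, np.float32)
        dx[:, 0::2, 0::2, :] = dout * ma
        dx[:, 0::2, 1::2, :] = dout * mb
        dx[:, 1::2, 0::2, :] = dout * mc
        dx[:, 1::2, 1::2, :] = dout * md
        self._masks = None
        return dx


class UpsampleNearest2:
    """Nearest-neighbour x2 upsampling; backward sums each 2x2 block."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return (
            dout[:, 0::2, 0::2, :]
            + dout[:, 0::2, 1::2, :]
            + dout[:, 1::2, 0::2, :]
            + dout[:, 1::2, 1::2, :]
        )


class Dropout:
    """Inverted dropout; active only during training."""

    def __init__(self, rate: float):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, rng: np.random.Generator, train: bool = True) -> np.ndarray:
        if not train or self.rate == 0:
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        dx = dout * self._mask
        self._mask = None
        return dx


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean per-pixel cross-entropy and its gradient w.r.t. logits.

    ``logits``: (N, H, W, K); ``targets``: (N, H, W) integer class labels.
    """
    p = softmax(logits, axis=-1)
    n, h, w, k = logits.shape
    idx = targets[..., None]
    picked = np.take_along_axis(p, idx, axis=-1)[..., 0]
    loss = float(-np.log(np.clip(picked, 1e-12, None)).mean())
    onehot = np.zeros_like(p)
    np.put_along_axis(onehot, idx, 1.0, axis=-1)
    dlogits = (p - onehot) / (n * h * w)
    return loss, dlogits.astype(np.float32)
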