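"""Minimal numpy layer library with explicit backpropagation.

Only what the U-Net needs: padded 3x3 (and 1x1) convolutions, batch
normalization, ReLU, 2x2 max pooling, and 2x2 stride-2 transposed
convolutions.  Activations flow in channels-last layout (N, H, W, C) —
the fastest arrangement for the shift-stack GEMM convolutions used here —
while parameters keep the canonical (C_out, C_in, k, k) shape so counting
and flattening are layout-independent.  Every layer caches what its
backward pass needs and accumulates parameter gradients in ``.grads``.

All arrays are float32; forward/backward are deterministic for fixed inputs.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Layer:
    """Base: parameters as an ordered dict of arrays, grads mirrored."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def zero_grads(self):
        for k, v in self.params.items():
            self.grads[k] = np.zeros_like(v)

    def n_params(self) -> int:
        return int(sum(v.size for v in self.params.values()))


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N,H,W,C) -> contiguous (N*H*W, k*k*C) patch matrix, 'same' padding."""
    n, h, w, c = x.shape
    pad = k // 2
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    cols = np.empty((n, h, w, k * k, c), dtype=x.dtype)
    i = 0
    for u in range(k):
        for v in range(k):
            cols[:, :, :, i, :] = xp[:, u : u + h, v : v + w, :]
            i += 1
    return cols.reshape(n * h * w, k * k * c)


class Conv2d(Layer):
    """Padded kxk convolution (k in {1, 3}), stride 1, He-initialized."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        super().__init__()
        if k not in (1, 3):
            raise ValueError("only 1x1 and 3x3 kernels are used here")
        self.c_in, self.c_out, self.k = c_in, c_out, k
        std = np.sqrt(2.0 / (c_in * k * k))
        self.params["W"] = (std * rng.standard_normal((c_out, c_in, k, k))).astype(DTYPE)
        self.params["b"] = np.zeros(c_out, dtype=DTYPE)
        self.zero_grads()
        self._cols = None
        self._x_shape = None

    def _w_mat(self) -> np.ndarray:
        # (k*k*C_in, C_out), patch-index-major to match _im2col ordering
        return self.params["W"].transpose(2, 3, 1, 0).reshape(-1, self.c_out)

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        cols = x.reshape(n * h * w, c) if self.k == 1 else _im2col(x, self.k)
        self._cols = cols
        self._x_shape = x.shape
        y = cols @ self._w_mat() + self.params["b"]
        return y.reshape(n, h, w, self.c_out)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._x_shape
        k = self.k
        dyf = dy.reshape(n * h * w, self.c_out)
        dwm = self._cols.T @ dyf  # (k*k*C_in, C_out)
        self.grads["W"] += dwm.reshape(k, k, c, self.c_out).transpose(3, 2, 0, 1)
        self.grads["b"] += dyf.sum(axis=0)
        if k == 1:
            dx = dyf @ self.params["W"].reshape(self.c_out, c)
        else:
            # full correlation with the flipped kernel
            cols2 = _im2col(dy, k)  # (N*H*W, k*k*C_out)
            wb = (
                self.params["W"][:, :, ::-1, ::-1]
                .transpose(2, 3, 0, 1)
                .reshape(k * k * self.c_out, c)
            )
            dx = cols2 @ wb
        self._cols = None
        return dx.reshape(n, h, w, c)


class ConvTranspose2d(Layer):
    """2x2, stride-2 transposed convolution (learned upsampling)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        self.c_in, self.c_out = c_in, c_out
        std = np.sqrt(2.0 / (c_in * 4))
        self.params["W"] = (std * rng.standard_normal((c_in, c_out, 2, 2))).astype(DTYPE)
        self.params["b"] = np.zeros(c_out, dtype=DTYPE)
        self.zero_grads()
        self._x = None

    def _w_mat(self) -> np.ndarray:
        # (C_in, 2*2*C_out), offset-major
        return self.params["W"].transpose(0, 2, 3, 1).reshape(self.c_in, -1)

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        self._x = x
        t = x.reshape(n * h * w, c) @ self._w_mat()
        t = t.reshape(n, h, w, 2, 2, self.c_out).transpose(0, 1, 3, 2, 4, 5)
        y = t.reshape(n, 2 * h, 2 * w, self.c_out)
        return y + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        n, h, w, c = x.shape
        dyr = (
            dy.reshape(n, h, 2, w, 2, self.c_out)
            .transpose(0, 1, 3, 2, 4, 5)
            .reshape(n * h * w, 4 * self.c_out)
        )
        dwm = x.reshape(n * h * w, c).T @ dyr  # (C_in, 4*C_out)
        self.grads["W"] += dwm.reshape(c, 2, 2, self.c_out).transpose(0, 3, 1, 2)
        self.grads["b"] += dy.sum(axis=(0, 1, 2))
        dx = dyr @ self._w_mat().T
        self._x = None
        return dx.reshape(n, h, w, c)


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics.

    ``frozen`` pins both the affine parameters (the model's freeze mask
    skips their update) and the running statistics: a frozen layer always
    normalizes with its stored statistics and never updates them.
    """

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.c = c
        self.momentum = momentum
        self.eps = eps
        self.params["gamma"] = np.ones(c, dtype=DTYPE)
        self.params["beta"] = np.zeros(c, dtype=DTYPE)
        self.zero_grads()
        self.running_mean = np.zeros(c, dtype=DTYPE)
        self.running_var = np.ones(c, dtype=DTYPE)
        self.frozen = False
        self._cache = None

    def forward(self, x: np.ndarray, train: bool, update_stats: bool) -> np.ndarray:
        if train and not self.frozen:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            if update_stats:
                m = self.momentum
                self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(DTYPE)
                self.running_var = ((1 - m) * self.running_var + m * var).astype(DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = (1.0 / np.sqrt(var + self.eps)).astype(DTYPE)
        xhat = (x - mean) * invstd
        self._cache = (xhat, invstd, train and not self.frozen)
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, invstd, batch_mode = self._cache
        dgamma = np.sum(dy * xhat, axis=(0, 1, 2))
        dbeta = np.sum(dy, axis=(0, 1, 2))
        self.grads["gamma"] += dgamma
        self.grads["beta"] += dbeta
        g = self.params["gamma"] * invstd
        self._cache = None
        if not batch_mode:
            return dy * g
        n = dy.shape[0] * dy.shape[1] * dy.shape[2]
        return (g / n) * (n * dy - dbeta - xhat * dgamma)


class ReLU(Layer):
    def __init__(self):
        super().__init__()
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy * self._mask
        self._mask = None
        return dx


class MaxPool2d(Layer):
    """2x2, stride-2 max pooling."""

    def __init__(self):
        super().__init__()
        self._arg = None
        self._shape = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        xr = (
            x.reshape(n, h // 2, 2, w // 2, 2, c)
            .transpose(0, 1, 3, 5, 2, 4)
            .reshape(n, h // 2, w // 2, c, 4)
        )
        self._arg = xr.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(xr, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        out = np.zeros((n, h // 2, w // 2, c, 4), dtype=dy.dtype)
        np.put_along_axis(out, self._arg[..., None], dy[..., None], axis=-1)
        dx = (
            out.reshape(n, h // 2, w // 2, c, 2, 2)
            .transpose(0, 1, 4, 2, 5, 3)
            .reshape(n, h, w, c)
        )
        self._arg = None
        return dx
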