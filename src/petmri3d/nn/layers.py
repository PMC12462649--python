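"""Primitive layers with manual forward/backward passes.

Every layer caches what its backward pass needs during ``forward`` and
exposes ``params`` / ``grads`` dictionaries consumed by the optimiser.
Convolutions are evaluated as one matmul per kernel offset (27 for a
3x3x3 kernel), which keeps the arithmetic in BLAS without materialising
a full im2col buffer.
"""

from __future__ import annotations

from itertools import product

import numpy as np

__all__ = ["Layer", "Conv3d", "BatchNorm", "ReLU", "Dense", "global_avg_pool"]


class Layer:
    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def zero_grad(self) -> None:
        for k in self.params:
            self.grads[k] = np.zeros_like(self.params[k])


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv3d(Layer):
    """3D convolution with 'same' padding (pad = kernel // 2).

    Output spatial size along each axis is ``ceil(D / stride)`` for odd
    kernels, so stride-2 convolutions halve the grid. Evaluated as an
    im2col matrix product: the padded input is unfolded once into a
    ``(n_windows, cin * k^3)`` matrix and hit with the flattened kernel,
    which keeps the arithmetic inside one BLAS call.
    """

    def __init__(self, cin: int, cout: int, kernel: int, stride: int, rng: np.random.Generator):
        super().__init__()
        self.cin, self.cout, self.k, self.s = cin, cout, kernel, stride
        self.pad = kernel // 2
        fan_in = cin * kernel**3
        self.params = {
            "W": _he_init(rng, (cout, cin, kernel, kernel, kernel), fan_in),
            "b": np.zeros(cout, dtype=np.float32),
        }
        self.zero_grad()
        self._cols: np.ndarray | None = None

    def out_shape(self, spatial: tuple[int, int, int]) -> tuple[int, int, int]:
        return tuple((d + 2 * self.pad - self.k) // self.s + 1 for d in spatial)

    def _unfold(self, xp: np.ndarray, oshape) -> np.ndarray:
        """Padded input -> (n, o1*o2*o3, cin * k^3) column matrix."""
        n = xp.shape[0]
        view = np.lib.stride_tricks.sliding_window_view(
            xp, (self.k, self.k, self.k), axis=(2, 3, 4)
        )[:, :, :: self.s, :: self.s, :: self.s]
        # (n, cin, o1, o2, o3, k, k, k) -> (n, o1, o2, o3, cin, k, k, k)
        cols = np.ascontiguousarray(view.transpose(0, 2, 3, 4, 1, 5, 6, 7))
        return cols.reshape(n, -1, self.cin * self.k**3)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, cin = x.shape[:2]
        if cin != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {cin}")
        self._in_spatial = x.shape[2:]
        o1, o2, o3 = oshape = self.out_shape(x.shape[2:])
        if self.k == 1:
            # pointwise channel mixing: a single (cout, cin) matmul
            xs = x[:, :, :: self.s, :: self.s, :: self.s] if self.s > 1 else x
            self._x1 = xs.reshape(n, cin, -1)
            out = np.matmul(self.params["W"].reshape(self.cout, cin), self._x1)
            out = out.reshape(n, self.cout, o1, o2, o3)
            return out + self.params["b"][None, :, None, None, None]
        p = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p))) if p else x
        cols = self._unfold(xp, oshape)
        Wmat = self.params["W"].reshape(self.cout, -1)
        out = cols.reshape(-1, cols.shape[-1]) @ Wmat.T + self.params["b"]
        self._cols = cols
        self._oshape = oshape
        self._pshape = xp.shape
        return np.ascontiguousarray(
            out.reshape(n, o1, o2, o3, self.cout).transpose(0, 4, 1, 2, 3)
        )

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n = dout.shape[0]
        if self.k == 1:
            d1 = dout.reshape(n, self.cout, -1)
            self.grads["W"] += np.einsum("nos,ncs->oc", d1, self._x1, optimize=True
                                         ).reshape(self.params["W"].shape)
            self.grads["b"] += d1.sum(axis=(0, 2))
            dxs = np.matmul(self.params["W"].reshape(self.cout, self.cin).T, d1)
            if self.s == 1:
                return dxs.reshape((n, self.cin) + self._in_spatial)
            dx = np.zeros((n, self.cin) + self._in_spatial, dtype=np.float32)
            dx[:, :, :: self.s, :: self.s, :: self.s] = dxs.reshape(
                (n, self.cin) + tuple(dout.shape[2:])
            )
            return dx
        o1, o2, o3 = self._oshape
        dmat = np.ascontiguousarray(dout.transpose(0, 2, 3, 4, 1)).reshape(-1, self.cout)
        cols = self._cols.reshape(-1, self._cols.shape[-1])
        self.grads["W"] += (dmat.T @ cols).reshape(self.params["W"].shape)
        self.grads["b"] += dmat.sum(axis=0)
        Wmat = self.params["W"].reshape(self.cout, -1)
        dcols = (dmat @ Wmat).reshape(n, o1, o2, o3, self.cin, self.k, self.k, self.k)
        # (n, cin, o1, o2, o3, ki, kj, kl), one contiguous copy
        dct = np.ascontiguousarray(dcols.transpose(0, 4, 1, 2, 3, 5, 6, 7))
        # fold back (scatter-add); within one kernel offset the strided
        # targets are disjoint, overlaps occur only across offsets
        dxp = np.zeros(self._pshape, dtype=np.float32)
        for i, j, l in product(range(self.k), repeat=3):
            dxp[
                :, :,
                i : i + self.s * (o1 - 1) + 1 : self.s,
                j : j + self.s * (o2 - 1) + 1 : self.s,
                l : l + self.s * (o3 - 1) + 1 : self.s,
            ] += dct[:, :, :, :, :, i, j, l]
        p = self.pad
        if p:
            d1, d2_, d3 = self._in_spatial
            return dxp[:, :, p : p + d1, p : p + d2_, p : p + d3]
        return dxp


class BatchNorm(Layer):
    """Per-channel batch normalisation over batch and spatial axes.

    Training mode uses batch statistics and updates running estimates
    (momentum 0.9); evaluation mode uses the running estimates, so
    inference on a duplicated batch duplicates outputs exactly.
    """

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.params = {
            "gamma": np.ones(c, dtype=np.float32),
            "beta": np.zeros(c, dtype=np.float32),
        }
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.zero_grad()

    @staticmethod
    def _bc(v: np.ndarray, ndim: int) -> np.ndarray:
        return v.reshape((1, -1) + (1,) * (ndim - 2))

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        axes = (0,) + tuple(range(2, x.ndim))
        if training:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = (m * self.running_mean + (1 - m) * mu).astype(np.float32)
            self.running_var = (m * self.running_var + (1 - m) * var).astype(np.float32)
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - self._bc(mu, x.ndim)) * self._bc(inv, x.ndim)
        self._cache = (xhat, inv, training, axes)
        return self._bc(self.params["gamma"], x.ndim) * xhat + self._bc(
            self.params["beta"], x.ndim
        )

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv, training, axes = self._cache
        g = self._bc(self.params["gamma"], dout.ndim)
        self.grads["gamma"] += (dout * xhat).sum(axis=axes)
        self.grads["beta"] += dout.sum(axis=axes)
        if not training:
            return dout * g * self._bc(inv, dout.ndim)
        m = float(np.prod([dout.shape[a] for a in axes]))
        dsum = self._bc(dout.sum(axis=axes), dout.ndim)
        dxsum = self._bc((dout * xhat).sum(axis=axes), dout.ndim)
        return (g * self._bc(inv, dout.ndim) / m) * (m * dout - dsum - xhat * dxsum)


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class Dense(Layer):
    def __init__(self, fin: int, fout: int, rng: np.random.Generator):
        super().__init__()
        self.params = {
            "W": _he_init(rng, (fin, fout), fin),
            "b": np.zeros(fout, dtype=np.float32),
        }
        self.zero_grad()

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["W"] += self._x.T @ dout
        self.grads["b"] += dout.sum(axis=0)
        return dout @ self.params["W"].T


def global_avg_pool(x: np.ndarray) -> tuple[np.ndarray, tuple]:
    """Mean over all spatial axes; returns (pooled (N, C), input shape)."""
    return x.mean(axis=(2, 3, 4)), x.shape


def global_avg_pool_backward(dout: np.ndarray, in_shape: tuple) -> np.ndarray:
    n_vox = in_shape[2] * in_shape[3] * in_shape[4]
    return np.broadcast_to(
        dout[:, :, None, None, None] / n_vox, in_shape
    ).astype(np.float32)
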