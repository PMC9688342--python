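"""Minimal CPU neural-network backend (channels-last numpy tensors).

This module is the compute engine behind the segmentation networks: 2D/3D
convolutions via im2col GEMMs, batch normalization, pooling, dense layers,
softmax and the Adam optimizer, each with hand-written backward passes.

Conventions
-----------
* 3D feature maps are ``(N, D, H, W, C)`` float32, 2D maps ``(N, H, W, C)``.
* Convolutions are stride-1, odd-kernel, "same" zero padding.
* Layers cache persistent im2col buffers keyed by input shape; large scratch
  arrays are reused across steps rather than reallocated.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param", "Layer", "Conv", "BatchNorm", "ReLU", "MaxPool", "Upsample3D",
    "Dense", "Flatten", "Dropout", "Softmax", "Sequential", "Adam",
    "glorot_uniform",
]


class Param:
    """A trainable (or running-statistic) array with its gradient slot."""

    __slots__ = ("value", "grad", "trainable", "name")

    def __init__(self, value: np.ndarray, trainable: bool = True, name: str = ""):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value) if trainable else None
        self.trainable = trainable
        self.name = name


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _offsets(k: int, ndim: int):
    from itertools import product

    return list(product(range(k), repeat=ndim))


class Conv(Layer):
    """Stride-1 same-padding convolution for 2D or 3D feature maps.

    Weights are stored as ``(k^ndim, c_in, c_out)``.  When the compiled
    microkernels are available (see :mod:`lnlevelseg._ckernels`) forward,
    weight-gradient and data-gradient passes run through them on persistent
    zero-halo buffers; otherwise an im2col GEMM path is used.  The data
    gradient is in both cases a full correlation of the zero-padded output
    gradient with the spatially flipped, channel-transposed kernel, so no
    scatter-add col2im is ever needed.

    ``input_grad=False`` marks a first layer whose input gradient nobody
    consumes; its backward skips the data-gradient pass and returns None.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, ndim: int,
                 rng: np.random.Generator, bias: bool = False,
                 input_grad: bool = True):
        if kernel % 2 != 1:
            raise ValueError("only odd kernels supported")
        self.c_in, self.c_out, self.k, self.ndim = c_in, c_out, kernel, ndim
        kk = kernel ** ndim
        fan_in, fan_out = kk * c_in, kk * c_out
        self.W = Param(glorot_uniform(rng, (kk, c_in, c_out), fan_in, fan_out), name="W")
        self.b = Param(np.zeros(c_out, np.float32), name="b") if bias else None
        self.input_grad = input_grad
        self._bufs: dict = {}
        self._x_shape = None
        self._col = None
        from ._ckernels import get_lib
        self._lib = get_lib() if kernel == 3 else None
        self._kshape = ((3,) * ndim if ndim == 3 else (1, 3, 3)) if kernel == 3 else None

    def params(self):
        return [self.W] + ([self.b] if self.b is not None else [])

    # -- buffer management -------------------------------------------------
    def _get(self, key, shape):
        buf = self._bufs.get(key)
        if buf is None or buf.shape != tuple(shape):
            buf = np.zeros(shape, np.float32)
            self._bufs[key] = buf
        return buf

    def _pad(self, x, c, key):
        """Copy x into a persistent zero-halo buffer (halo stays zero)."""
        n = x.shape[0]
        spatial = x.shape[1:-1]
        xp = self._get(key, (n,) + tuple(s + 2 for s in spatial) + (c,))
        inner = (slice(None),) + tuple(slice(1, 1 + s) for s in spatial) + (slice(None),)
        xp[inner] = x
        return xp

    @staticmethod
    def _pad16(m):
        return -(-m // 16) * 16

    def _w16(self, w3, key):
        """(kk, C, F) -> zero-padded (kk, C, pad16(F)) persistent copy."""
        kk, c, f = w3.shape
        w16 = self._get(key, (kk, c, self._pad16(f)))
        w16[:, :, :f] = w3
        return w16

    def _run_fwd(self, xp, w3, dims, key):
        """Blocked conv_fwd16 call; returns a (..., c_out) view."""
        from . import _ckernels
        n, d, h, wd, c = dims
        f = w3.shape[-1]
        fp = self._pad16(f)
        y16 = self._get(key, ((n, d, h, wd, fp) if self.ndim == 3
                              else (n, h, wd, fp)))
        w16 = self._w16(w3, key + "_w")
        for b in range(fp // 16):
            _ckernels.conv_fwd16(self._lib, xp, w16[:, :, b * 16:(b + 1) * 16],
                                 y16, dims, c, fp, b * 16, self._kshape)
        return y16[..., :f] if f != fp else y16

    # -- forward / backward ------------------------------------------------
    def forward(self, x, train=False):
        if x.dtype != np.float32:
            x = x.astype(np.float32)
        self._x_shape = x.shape
        n = x.shape[0]
        spatial = x.shape[1:-1]
        if self.k == 1:
            self._col = np.ascontiguousarray(x).reshape(-1, self.c_in)
            y = self._get("y1", (self._col.shape[0], self.c_out))
            np.matmul(self._col, self.W.value.reshape(self.c_in, self.c_out), out=y)
            out = y.reshape((n,) + tuple(spatial) + (self.c_out,))
        elif self._lib is not None:
            self._xp = self._pad(x, self.c_in, "xp")
            d, h, wd = spatial if self.ndim == 3 else (1, *spatial)
            self._dims = (n, d, h, wd, self.c_in)
            out = self._run_fwd(self._xp, self.W.value, self._dims, "y")
        else:
            self._col = self._im2col(x, self.c_in, "f")
            kk = self.k ** self.ndim
            y = self._get("y", (self._col.shape[0], self.c_out))
            np.matmul(self._col, self.W.value.reshape(kk * self.c_in, self.c_out),
                      out=y)
            out = y.reshape((n,) + tuple(spatial) + (self.c_out,))
        if self.b is not None:
            out = out + self.b.value
        return out

    def _im2col(self, x, c, key):
        """im2col fallback: fill the persistent col buffer for `x`."""
        n = x.shape[0]
        spatial = x.shape[1:-1]
        xp = self._pad(x, c, key + "_pad")
        kk = self.k ** self.ndim
        col = self._get(key + "_col", (n,) + tuple(spatial) + (kk, c))
        for j, off in enumerate(_offsets(self.k, self.ndim)):
            sl = (slice(None),) + tuple(
                slice(o, o + s) for o, s in zip(off, spatial)) + (slice(None),)
            col[..., j, :] = xp[sl]
        return col.reshape(-1, kk * c)

    def backward(self, gy):
        if gy.dtype != np.float32:
            gy = gy.astype(np.float32)
        kk = self.k ** self.ndim
        if self.k == 1:
            gy2 = np.ascontiguousarray(gy).reshape(-1, self.c_out)
            self.W.grad += (self._col.T @ gy2).reshape(self.W.grad.shape)
            if self.b is not None:
                self.b.grad += gy2.sum(axis=0)
            if not self.input_grad:
                return None
            gx = gy2 @ self.W.value.reshape(self.c_in, self.c_out).T
            return gx.reshape(self._x_shape)
        if self._lib is not None:
            return self._backward_ck(gy)
        gy2 = np.ascontiguousarray(gy).reshape(-1, self.c_out)
        self.W.grad += (self._col.T @ gy2).reshape(self.W.grad.shape)
        if self.b is not None:
            self.b.grad += gy2.sum(axis=0)
        if not self.input_grad:
            return None
        w3 = self.W.value
        w_flip = np.ascontiguousarray(
            w3[::-1].transpose(0, 2, 1).reshape(kk * self.c_out, self.c_in))
        gcol = self._im2col(gy, self.c_out, "b")
        gx = self._get("gx", (gcol.shape[0], self.c_in))
        np.matmul(gcol, w_flip, out=gx)
        return gx.reshape(self._x_shape)

    def _backward_ck(self, gy):
        from . import _ckernels
        kk = self.k ** self.ndim
        fp = self._pad16(self.c_out)
        n, d, h, wd, _ = self._dims
        # weight gradient: gy rows must be 16-wide
        gy16 = self._get("gy16", ((n, d, h, wd, 16) if self.ndim == 3
                                  else (n, h, wd, 16)))
        gw16 = self._get("gw16", (kk, self.c_in, 16))
        for b in range(fp // 16):
            width = min(16, self.c_out - b * 16)
            if width < 16:
                gy16.fill(0.0)
            gy16[..., :width] = gy[..., b * 16:b * 16 + width]
            gw16.fill(0.0)
            _ckernels.conv_gw16(self._lib, self._xp, gy16, gw16,
                                self._dims, self.c_in, self._kshape)
            self.W.grad[:, :, b * 16:b * 16 + width] += gw16[:, :, :width]
        if self.b is not None:
            self.b.grad += gy.reshape(-1, self.c_out).sum(axis=0)
        if not self.input_grad:
            return None
        # data gradient: full correlation with flipped, transposed kernel
        w_t = np.ascontiguousarray(self.W.value[::-1].transpose(0, 2, 1))
        gyp = self._pad(gy, self.c_out, "gyp")
        gdims = (n, d, h, wd, self.c_out)
        gx = self._run_fwd(gyp, w_t, gdims, "gx")
        return gx.reshape(self._x_shape) if gx.shape != self._x_shape else gx


class BatchNorm(Layer):
    """Batch normalization over all axes but the last (channel) axis."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(c, np.float32), name="gamma")
        self.beta = Param(np.zeros(c, np.float32), name="beta")
        self.running_mean = Param(np.zeros(c, np.float32), trainable=False)
        self.running_var = Param(np.ones(c, np.float32), trainable=False)
        self.momentum, self.eps = momentum, eps
        self._buf = None

    def _out(self, shape):
        if self._buf is None or self._buf.shape != shape:
            self._buf = np.empty(shape, np.float32)
        return self._buf

    def params(self):
        return [self.gamma, self.beta, self.running_mean, self.running_var]

    def forward(self, x, train=False):
        c = x.shape[-1]
        x2 = x.reshape(-1, c)
        if train:
            m = x2.shape[0]
            s1 = np.einsum("nc->c", x2, dtype=np.float64)
            s2 = np.einsum("nc,nc->c", x2, x2, dtype=np.float64)
            mean = (s1 / m).astype(np.float32)
            var = np.maximum(s2 / m - mean.astype(np.float64) ** 2, 0.0).astype(np.float32)
            mom = self.momentum
            self.running_mean.value[:] = mom * self.running_mean.value + (1 - mom) * mean
            self.running_var.value[:] = mom * self.running_var.value + (1 - mom) * var
        else:
            mean, var = self.running_mean.value, self.running_var.value
        self._inv = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        self._mean = mean
        self._x = x
        self._train = train
        # y = a*x + b, folded per channel, written into a reused buffer
        a = self.gamma.value * self._inv
        b = self.beta.value - a * mean
        out = self._out(x.shape)
        np.multiply(x, a, out=out)
        out += b
        return out

    def backward(self, gy):
        c = gy.shape[-1]
        gy2 = gy.reshape(-1, c)
        x2 = self._x.reshape(-1, c)
        m = gy2.shape[0]
        sg = np.einsum("nc->c", gy2, dtype=np.float64).astype(np.float32)
        sgx = np.einsum("nc,nc->c", gy2, x2, dtype=np.float64).astype(np.float32)
        # sum gy * xhat, from the raw-x sums
        sgxh = (sgx - self._mean * sg) * self._inv
        self.gamma.grad += sgxh
        self.beta.grad += sg
        ginv = self.gamma.value * self._inv
        if not self._train:
            return gy * ginv
        gxh_mean = sgxh / m
        gm = sg / m
        # gx = A*gy + B*x + C with per-channel constants; gy is consumed
        # in place (every producer hands over a fresh or reusable array)
        a = ginv
        b = -ginv * gxh_mean * self._inv
        const = -ginv * gm - b * self._mean
        gx = np.multiply(gy, a, out=gy if gy.flags.writeable else None)
        gx += self._x * b
        gx += const
        return gx


class ReLU(Layer):
    """Rectifier; clips its (always freshly-computed) input in place."""

    def forward(self, x, train=False):
        y = np.maximum(x, 0.0, out=x)
        self._y = y
        return y

    def backward(self, gy):
        return gy * (self._y > 0)


class MaxPool(Layer):
    """2x (per spatial axis) max pooling for 2D or 3D maps."""

    def __init__(self, ndim: int):
        self.ndim = ndim

    def _blocked(self, x):
        n, c = x.shape[0], x.shape[-1]
        spatial = x.shape[1:-1]
        shape = (n,)
        for s in spatial:
            shape += (s // 2, 2)
        shape += (c,)
        return x.reshape(shape)

    def forward(self, x, train=False):
        self._x = x
        xb = self._blocked(x)
        axes = tuple(2 + 2 * i for i in range(self.ndim))
        y = xb.max(axis=axes)
        self._y = y
        return y

    def backward(self, gy):
        x = self._x
        up = self._y
        gup = gy
        for i in range(self.ndim):
            ax = 1 + i
            up = np.repeat(up, 2, axis=ax)
            gup = np.repeat(gup, 2, axis=ax)
        mask = x == up
        return (mask * gup).astype(np.float32, copy=False)


class Upsample3D(Layer):
    """Nearest-neighbour 2x upsampling of (N, D, H, W, C) maps."""

    def forward(self, x, train=False):
        y = x
        for ax in (1, 2, 3):
            y = np.repeat(y, 2, axis=ax)
        return y

    def backward(self, gy):
        n, d, h, w, c = gy.shape
        g = gy.reshape(n, d // 2, 2, h // 2, 2, w // 2, 2, c)
        return np.ascontiguousarray(g.sum(axis=(2, 4, 6)))


class Dense(Layer):
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.W = Param(glorot_uniform(rng, (c_in, c_out), c_in, c_out), name="W")
        self.b = Param(np.zeros(c_out, np.float32), name="b")

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, gy):
        self.W.grad += self._x.T @ gy
        self.b.grad += gy.sum(axis=0)
        return gy @ self.W.value.T


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gy):
        return gy.reshape(self._shape)


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, p: float, rng: np.random.Generator):
        self.p = float(p)
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.p <= 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, gy):
        if self._mask is None:
            return gy
        return gy * self._mask


class Softmax(Layer):
    """Softmax over the last axis."""

    def forward(self, x, train=False):
        z = x - x.max(axis=-1, keepdims=True)
        e = np.exp(z)
        self._q = e / e.sum(axis=-1, keepdims=True)
        return self._q

    def backward(self, gy):
        q = self._q
        dot = (gy * q).sum(axis=-1, keepdims=True)
        return (q * (gy - dot)).astype(np.float32, copy=False)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)

    def params(self):
        out = []
        for l in self.layers:
            out.extend(l.params())
        return out

    def forward(self, x, train=False):
        for l in self.layers:
            x = l.forward(x, train=train)
        return x

    def backward(self, gy):
        for l in reversed(self.layers):
            gy = l.backward(gy)
        return gy


class Adam:
    """Adam with the defaults used for training (lr set externally per step)."""

    def __init__(self, params: list[Param], beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7):
        self.params = [p for p in params if p.trainable]
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad.fill(0.0)

    def step(self, lr: float):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1.0 - b1 ** self.t
        c2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.value -= lr * (m / c1) / (np.sqrt(v / c2) + self.eps)
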