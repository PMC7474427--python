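"""Layer primitives with explicit forward/backward passes.

Conventions
-----------
* Images travel as ``(N, C, H, W)`` arrays, dense features as ``(N, D)``.
* ``forward(x, train=..., rng=...)`` caches whatever ``backward`` needs; a layer
  instance is therefore not reentrant, which is fine for the sequential
  networks built here.
* Parameters are ``Param`` objects so optimizers can mutate values in place and
  read accumulated gradients.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv2d",
    "ConvTranspose2d",
    "Dense",
    "BatchNorm",
    "Dropout",
    "Flatten",
    "MaxPool2d",
    "ReLU",
    "LeakyReLU",
    "Tanh",
    "Sigmoid",
    "Softplus",
    "Softmax",
]


class Param:
    """A trainable tensor and its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Layer:
    """Base class; stateless layers only need ``forward``/``backward``."""

    params: tuple = ()

    def forward(self, x, *, train=False, rng=None):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - interface
        raise NotImplementedError


# ---------------------------------------------------------------------------
# im2col machinery


def _im2col(x, k, stride, pad):
    """Lower sliding k*k patches of ``x`` (N,C,H,W) to columns (N, C*k*k, L)."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    windows = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    windows = windows[:, :, ::stride, ::stride]
    n, c, ho, wo, _, _ = windows.shape
    cols = windows.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * k * k, ho * wo)
    return np.ascontiguousarray(cols), ho, wo


def _col2im(dcols, x_shape, k, stride, pad, ho, wo):
    """Adjoint of :func:`_im2col`: scatter-add columns back onto the input grid."""
    n, c, h, w = x_shape
    dx = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    dcols = dcols.reshape(n, c, k, k, ho, wo)
    for i in range(k):
        for j in range(k):
            dx[:, :, i : i + ho * stride : stride, j : j + wo * stride : stride] += dcols[
                :, :, i, j
            ]
    if pad:
        dx = dx[:, :, pad : pad + h, pad : pad + w]
    return dx


def _init_weight(rng, shape, fan_in, scheme, dtype):
    if scheme == "he":
        std = np.sqrt(2.0 / fan_in)
    elif scheme == "dcgan":
        std = 0.02
    else:
        raise ValueError(f"unknown init scheme {scheme!r}")
    return rng.normal(0.0, std, size=shape).astype(dtype)


class Conv2d(Layer):
    """Strided 2-D convolution (cross-correlation) with zero padding."""

    def __init__(self, in_ch, out_ch, kernel=3, stride=1, pad=1, *, rng, init="he",
                 dtype=np.float32):
        self.in_ch, self.out_ch = in_ch, out_ch
        self.k, self.stride, self.pad = kernel, stride, pad
        fan_in = in_ch * kernel * kernel
        self.W = Param(_init_weight(rng, (out_ch, fan_in), fan_in, init, dtype))
        self.b = Param(np.zeros(out_ch, dtype=dtype))
        self.params = (self.W, self.b)

    def forward(self, x, *, train=False, rng=None):
        cols, ho, wo = _im2col(x, self.k, self.stride, self.pad)
        out = np.matmul(self.W.value, cols) + self.b.value[:, None]
        self._cache = (x.shape, cols, ho, wo)
        return out.reshape(x.shape[0], self.out_ch, ho, wo)

    def backward(self, dout):
        x_shape, cols, ho, wo = self._cache
        n = x_shape[0]
        dflat = dout.reshape(n, self.out_ch, ho * wo)
        self.W.grad += np.tensordot(dflat, cols, axes=([0, 2], [0, 2]))
        self.b.grad += dflat.sum(axis=(0, 2))
        dcols = np.matmul(self.W.value.T, dflat)
        return _col2im(dcols, x_shape, self.k, self.stride, self.pad, ho, wo)


class ConvTranspose2d(Layer):
    """Fractionally strided (transposed) convolution.

    Realized as zero-insertion upsampling followed by a stride-1 convolution
    with the spatially flipped kernel, which is numerically identical to the
    usual gradient-of-convolution definition. Output size is
    ``(H-1)*stride - 2*pad + kernel + output_pad``.
    """

    def __init__(self, in_ch, out_ch, kernel=3, stride=2, pad=1, output_pad=1, *,
                 rng, init="dcgan", dtype=np.float32):
        self.in_ch, self.out_ch = in_ch, out_ch
        self.k, self.stride, self.pad, self.output_pad = kernel, stride, pad, output_pad
        if kernel - 1 - pad < 0:
            raise ValueError("pad may not exceed kernel-1")
        fan_in = in_ch * kernel * kernel
        # native layout (in_ch, out_ch, k, k); flipped to conv form on the fly
        self.W = Param(_init_weight(rng, (in_ch, out_ch, kernel, kernel), fan_in, init, dtype))
        self.b = Param(np.zeros(out_ch, dtype=dtype))
        self.params = (self.W, self.b)

    def _conv_weight(self):
        w = self.W.value[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
        return np.ascontiguousarray(w).reshape(self.out_ch, self.in_ch * self.k * self.k)

    def forward(self, x, *, train=False, rng=None):
        n, c, h, w = x.shape
        s, op = self.stride, self.output_pad
        hu, wu = (h - 1) * s + 1 + op, (w - 1) * s + 1 + op
        x_up = np.zeros((n, c, hu, wu), dtype=x.dtype)
        x_up[:, :, ::s, ::s][:, :, :h, :w] = x
        p = self.k - 1 - self.pad
        cols, ho, wo = _im2col(x_up, self.k, 1, p)
        out = np.matmul(self._conv_weight(), cols) + self.b.value[:, None]
        self._cache = (x.shape, x_up.shape, cols, ho, wo)
        return out.reshape(n, self.out_ch, ho, wo)

    def backward(self, dout):
        x_shape, up_shape, cols, ho, wo = self._cache
        n, c, h, w = x_shape
        s = self.stride
        dflat = dout.reshape(n, self.out_ch, ho * wo)
        dwc = np.tensordot(dflat, cols, axes=([0, 2], [0, 2]))
        dwc = dwc.reshape(self.out_ch, self.in_ch, self.k, self.k)
        self.W.grad += dwc.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1]
        self.b.grad += dflat.sum(axis=(0, 2))
        dcols = np.matmul(self._conv_weight().T, dflat)
        dx_up = _col2im(dcols, up_shape, self.k, 1, self.k - 1 - self.pad, ho, wo)
        return dx_up[:, :, ::s, ::s][:, :, :h, :w]


class Dense(Layer):
    def __init__(self, in_dim, out_dim, *, rng, init="he", dtype=np.float32):
        self.W = Param(_init_weight(rng, (in_dim, out_dim), in_dim, init, dtype))
        self.b = Param(np.zeros(out_dim, dtype=dtype))
        self.params = (self.W, self.b)

    def forward(self, x, *, train=False, rng=None):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dout):
        self.W.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.W.value.T


class BatchNorm(Layer):
    """Batch normalization over the batch (and spatial dims for 4-D input).

    ``momentum`` follows the convention ``running = momentum*running +
    (1-momentum)*batch`` so the default 0.8 keeps 80% of the running estimate
    per update.
    """

    def __init__(self, num_features, momentum=0.8, eps=1e-5, dtype=np.float32):
        self.momentum, self.eps = momentum, eps
        self.gamma = Param(np.ones(num_features, dtype=dtype))
        self.beta = Param(np.zeros(num_features, dtype=dtype))
        self.params = (self.gamma, self.beta)
        self.running_mean = np.zeros(num_features, dtype=dtype)
        self.running_var = np.ones(num_features, dtype=dtype)

    def _axes_and_shape(self, x):
        if x.ndim == 4:
            return (0, 2, 3), (1, -1, 1, 1)
        return (0,), (1, -1)

    def forward(self, x, *, train=False, rng=None):
        axes, shape = self._axes_and_shape(x)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = (m * self.running_mean + (1 - m) * mean).astype(
                self.running_mean.dtype
            )
            self.running_var = (m * self.running_var + (1 - m) * var).astype(
                self.running_var.dtype
            )
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(shape)) * inv_std.reshape(shape)
        self._cache = (xhat, inv_std, axes, shape)
        return self.gamma.value.reshape(shape) * xhat + self.beta.value.reshape(shape)

    def backward(self, dout):
        xhat, inv_std, axes, shape = self._cache
        self.gamma.grad += (dout * xhat).sum(axis=axes)
        self.beta.grad += dout.sum(axis=axes)
        dxhat = dout * self.gamma.value.reshape(shape)
        mean_d = dxhat.mean(axis=axes).reshape(shape)
        mean_dx = (dxhat * xhat).mean(axis=axes).reshape(shape)
        return inv_std.reshape(shape) * (dxhat - mean_d - xhat * mean_dx)


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, rate):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, *, train=False, rng=None):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("Dropout in training mode needs an RNG")
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask


class Flatten(Layer):
    def forward(self, x, *, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class MaxPool2d(Layer):
    """Non-overlapping max pooling (pool == stride)."""

    def __init__(self, pool=2):
        self.pool = pool

    def forward(self, x, *, train=False, rng=None):
        p = self.pool
        n, c, h, w = x.shape
        if h % p or w % p:
            raise ValueError("input spatial dims must be divisible by the pool size")
        xr = x.reshape(n, c, h // p, p, w // p, p).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // p, w // p, p * p)
        self._argmax = xr.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(xr, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        p = self.pool
        n, c, h, w = self._shape
        dxr = np.zeros((n, c, h // p, w // p, p * p), dtype=dout.dtype)
        np.put_along_axis(dxr, self._argmax[..., None], dout[..., None], axis=-1)
        dxr = dxr.reshape(n, c, h // p, w // p, p, p).transpose(0, 1, 2, 4, 3, 5)
        return dxr.reshape(n, c, h, w)


class ReLU(Layer):
    def forward(self, x, *, train=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class LeakyReLU(Layer):
    def __init__(self, alpha=0.2):
        self.alpha = alpha

    def forward(self, x, *, train=False, rng=None):
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, dout):
        return np.where(self._mask, dout, self.alpha * dout)


class Tanh(Layer):
    def forward(self, x, *, train=False, rng=None):
        self._out = np.tanh(x)
        return self._out

    def backward(self, dout):
        return dout * (1.0 - self._out**2)


class Sigmoid(Layer):
    def forward(self, x, *, train=False, rng=None):
        self._out = 1.0 / (1.0 + np.exp(-x))
        return self._out

    def backward(self, dout):
        return dout * self._out * (1.0 - self._out)


class Softplus(Layer):
    """softplus(a) = ln(1 + e^a), a smooth rectifier."""

    def forward(self, x, *, train=False, rng=None):
        self._x = x
        return np.logaddexp(0.0, x)

    def backward(self, dout):
        return dout / (1.0 + np.exp(-self._x))


class Softmax(Layer):
    """Row-wise softmax over the last axis."""

    def forward(self, x, *, train=False, rng=None):
        z = x - x.max(axis=-1, keepdims=True)
        e = np.exp(z)
        self._out = e / e.sum(axis=-1, keepdims=True)
        return self._out

    def backward(self, dout):
        p = self._out
        return p * (dout - (dout * p).sum(axis=-1, keepdims=True))
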