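"""Minimal trainable layer stack on numpy.

Supports exactly what the EEG convnets in :mod:`mbcl.networks` need: 2-D
convolution (valid / length-preserving padding, channel groups for depthwise
and separable variants), batch normalization, ELU / guarded-log / square
activations, average and max pooling with overlapping windows, dropout, dense
layers and a softmax head.  Forward passes cache whatever the backward pass
needs; parameter gradients accumulate into ``Param.grad``.

Array layout is (batch, feature_maps, height, width); an EEG crop enters as
(batch, 1, n_channels, n_samples) so that temporal kernels are (1, k) and
spatial kernels collapse the channel axis, mirroring the conventional
EEG-convnet formulation.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Sequential",
    "Conv2d",
    "BatchNorm",
    "Dense",
    "ELU",
    "LogClip",
    "Square",
    "AvgPool2d",
    "MaxPool2d",
    "Dropout",
    "Flatten",
    "softmax",
]


class Param:
    """A trainable tensor with its accumulated gradient."""

    __slots__ = ("data", "grad", "max_norm_axis", "max_norm")

    def __init__(self, data: np.ndarray, max_norm: float | None = None,
                 max_norm_axis: tuple[int, ...] | None = None):
        self.data = np.asarray(data)
        self.grad = np.zeros_like(self.data)
        self.max_norm = max_norm
        self.max_norm_axis = max_norm_axis

    def constrain(self) -> None:
        """Renormalize to the max-norm ball, if one was declared."""
        if self.max_norm is None:
            return
        norms = np.sqrt(np.sum(self.data ** 2, axis=self.max_norm_axis,
                               keepdims=True))
        scale = np.minimum(1.0, self.max_norm / np.maximum(norms, 1e-12))
        self.data *= scale


class Layer:
    """Base layer: stateless unless a subclass stores a cache."""

    training: bool = False

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []

    def set_training(self, flag: bool) -> None:
        self.training = flag

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self):
        out: list[Param] = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def set_training(self, flag):
        self.training = flag
        for layer in self.layers:
            layer.set_training(flag)


def _fan_in_uniform(rng: np.random.Generator, shape: tuple[int, ...],
                    fan_in: int, dtype) -> np.ndarray:
    limit = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


def _im2col(x: np.ndarray, kh: int, kw: int,
            sh: int = 1, sw: int = 1) -> np.ndarray:
    """(N, C, H, W) -> (N, Ho, Wo, C, kh, kw) window view (no copy)."""
    v = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    # v: (N, C, Ho', Wo', kh, kw) at stride 1 — subsample then reorder.
    v = v[:, :, ::sh, ::sw]
    return np.ascontiguousarray(v.transpose(0, 2, 3, 1, 4, 5))


class Conv2d(Layer):
    """Cross-correlation, stride 1, 'valid' or 'same' padding, channel groups.

    ``groups=c_in`` with ``c_out = multiplier*c_in`` gives a depthwise
    convolution; a unit max-norm constraint on each filter is available for
    the depthwise spatial filters of the compact architecture.
    """

    def __init__(self, c_in: int, c_out: int, kernel: tuple[int, int],
                 padding: str = "valid", groups: int = 1, bias: bool = True,
                 max_norm: float | None = None, *,
                 rng: np.random.Generator, dtype=np.float32):
        if c_in % groups or c_out % groups:
            raise ValueError("groups must divide both channel counts")
        self.c_in, self.c_out, self.groups = c_in, c_out, groups
        self.kh, self.kw = kernel
        if padding not in ("valid", "same"):
            raise ValueError(f"unknown padding {padding!r}")
        self.padding = padding
        cig = c_in // groups
        fan_in = cig * self.kh * self.kw
        w = _fan_in_uniform(rng, (c_out, cig, self.kh, self.kw), fan_in, dtype)
        self.w = Param(w, max_norm=max_norm, max_norm_axis=(1, 2, 3))
        self.b = Param(np.zeros(c_out, dtype=dtype)) if bias else None
        self._cache = None

    def _pad_amounts(self) -> tuple[tuple[int, int], tuple[int, int]]:
        if self.padding == "valid":
            return (0, 0), (0, 0)
        # 'same': total k-1, extra sample on the trailing side (TF convention)
        ph = ((self.kh - 1) // 2, self.kh // 2)
        pw = ((self.kw - 1) // 2, self.kw // 2)
        return ph, pw

    def forward(self, x):
        (pt, pb), (pl, pr) = self._pad_amounts()
        if pt or pb or pl or pr:
            xp = np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
        else:
            xp = x
        n = x.shape[0]
        g, cig, cog = self.groups, self.c_in // self.groups, self.c_out // self.groups
        cols = _im2col(xp, self.kh, self.kw)          # (N, Ho, Wo, C, kh, kw)
        ho, wo = cols.shape[1], cols.shape[2]
        if g > 1 and cig == 1:
            # depthwise: one einsum instead of a per-group loop
            wd = self.w.data.reshape(g, cog, self.kh, self.kw)
            y = np.einsum("nhwckl,cmkl->ncmhw", cols, wd, optimize=True)
            y = y.reshape(n, self.c_out, ho, wo)
        else:
            ys = []
            for gi in range(g):
                c = cols[:, :, :, gi * cig:(gi + 1) * cig]
                c = c.reshape(n * ho * wo, cig * self.kh * self.kw)
                wmat = self.w.data[gi * cog:(gi + 1) * cog].reshape(cog, -1)
                ys.append(c @ wmat.T)
            y = np.concatenate(ys, axis=1).reshape(n, ho, wo, self.c_out)
            y = y.transpose(0, 3, 1, 2)
        if self.b is not None:
            y = y + self.b.data[None, :, None, None]
        self._cache = (xp, x.shape)
        return np.ascontiguousarray(y)

    def backward(self, grad):
        xp, xshape = self._cache
        n = grad.shape[0]
        g, cig, cog = self.groups, self.c_in // self.groups, self.c_out // self.groups
        ho, wo = grad.shape[2], grad.shape[3]
        if self.b is not None:
            self.b.grad += grad.sum(axis=(0, 2, 3))
        cols = _im2col(xp, self.kh, self.kw)          # (N, Ho, Wo, C, kh, kw)
        dxp = np.zeros_like(xp)
        if g > 1 and cig == 1:
            # depthwise: einsum over maps, then per-tap scatter for dx
            gd = grad.reshape(n, g, cog, ho, wo)
            dw = np.einsum("nhwckl,ncmhw->cmkl", cols, gd, optimize=True)
            self.w.grad += dw.reshape(self.c_out, 1, self.kh, self.kw)
            wd = self.w.data.reshape(g, cog, self.kh, self.kw)
            dcols = np.einsum("ncmhw,cmkl->nhwckl", gd, wd, optimize=True)
            for i in range(self.kh):
                for j in range(self.kw):
                    dxp[:, :, i:i + ho, j:j + wo] += \
                        dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        else:
            gmat = grad.transpose(0, 2, 3, 1).reshape(n * ho * wo, self.c_out)
            for gi in range(g):
                c = cols[:, :, :, gi * cig:(gi + 1) * cig]
                c = c.reshape(n * ho * wo, cig * self.kh * self.kw)
                gg = gmat[:, gi * cog:(gi + 1) * cog]
                dw = gg.T @ c
                self.w.grad[gi * cog:(gi + 1) * cog] += dw.reshape(
                    cog, cig, self.kh, self.kw)
                # per-tap scatter (kernels are short for these nets)
                wmat = self.w.data[gi * cog:(gi + 1) * cog]
                dcols = (gg @ wmat.reshape(cog, -1)).reshape(
                    n, ho, wo, cig, self.kh, self.kw)
                for i in range(self.kh):
                    for j in range(self.kw):
                        dxp[:, gi * cig:(gi + 1) * cig,
                            i:i + ho, j:j + wo] += \
                            dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        (pt, _pb), (pl, _pr) = self._pad_amounts()
        h, w = xshape[2], xshape[3]
        return dxp[:, :, pt:pt + h, pl:pl + w]

    def params(self):
        return [self.w] + ([self.b] if self.b is not None else [])


class BatchNorm(Layer):
    """Per-feature-map batch normalization over (N, H, W)."""

    def __init__(self, num_features: int, momentum: float = 0.99,
                 eps: float = 1e-3, dtype=np.float32):
        self.gamma = Param(np.ones(num_features, dtype=dtype))
        self.beta = Param(np.zeros(num_features, dtype=dtype))
        self.running_mean = np.zeros(num_features, dtype=dtype)
        self.running_var = np.ones(num_features, dtype=dtype)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def forward(self, x):
        axes = (0, 2, 3) if x.ndim == 4 else (0,)
        shape = (1, -1, 1, 1) if x.ndim == 4 else (1, -1)
        if self.training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(shape)) * inv.reshape(shape)
        self._cache = (xhat, inv, axes, shape, x.shape)
        return self.gamma.data.reshape(shape) * xhat + self.beta.data.reshape(shape)

    def backward(self, grad):
        xhat, inv, axes, shape, xshape = self._cache
        m = np.prod([xshape[a] for a in axes])
        self.gamma.grad += (grad * xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        gx = grad * self.gamma.data.reshape(shape)
        if not self.training:
            return gx * inv.reshape(shape)
        # standard batch-norm gradient through batch statistics
        t1 = gx - gx.mean(axis=axes, keepdims=True)
        t2 = xhat * (gx * xhat).sum(axis=axes, keepdims=True) / m
        return inv.reshape(shape) * (t1 - t2)

    def params(self):
        return [self.gamma, self.beta]


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, *, rng: np.random.Generator,
                 dtype=np.float32):
        self.w = Param(_fan_in_uniform(rng, (d_in, d_out), d_in, dtype))
        self.b = Param(_fan_in_uniform(rng, (d_out,), d_in, dtype))
        self._x = None

    def forward(self, x):
        self._x = x
        return x @ self.w.data + self.b.data

    def backward(self, grad):
        self.w.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.w.data.T

    def params(self):
        return [self.w, self.b]


class ELU(Layer):
    def __init__(self, alpha: float = 1.0):
        self.alpha = alpha
        self._y = None

    def forward(self, x):
        y = np.where(x > 0, x, self.alpha * np.expm1(np.minimum(x, 0)))
        self._y = y
        return y

    def backward(self, grad):
        return grad * np.where(self._y > 0, 1.0, self._y + self.alpha)


class LogClip(Layer):
    """log(max(x, floor)) — guards the log-power activation against
    non-positive pooled values."""

    def __init__(self, floor: float = 1e-6):
        self.floor = floor
        self._x = None

    def forward(self, x):
        self._x = x
        return np.log(np.maximum(x, self.floor))

    def backward(self, grad):
        return grad * np.where(self._x > self.floor, 1.0 / np.maximum(self._x, self.floor), 0.0)


class Square(Layer):
    def __init__(self):
        self._x = None

    def forward(self, x):
        self._x = x
        return x * x

    def backward(self, grad):
        return 2.0 * self._x * grad


class AvgPool2d(Layer):
    """Average pooling; windows may overlap (stride < kernel)."""

    def __init__(self, kernel: tuple[int, int], stride: tuple[int, int] | None = None):
        self.kh, self.kw = kernel
        self.sh, self.sw = stride if stride is not None else kernel
        self._xshape = None

    def forward(self, x):
        v = np.lib.stride_tricks.sliding_window_view(x, (self.kh, self.kw),
                                                     axis=(2, 3))
        v = v[:, :, ::self.sh, ::self.sw]
        self._xshape = x.shape
        return v.mean(axis=(4, 5))

    def backward(self, grad):
        dx = np.zeros(self._xshape, dtype=grad.dtype)
        scale = 1.0 / (self.kh * self.kw)
        ho, wo = grad.shape[2], grad.shape[3]
        for i in range(ho):
            for j in range(wo):
                dx[:, :, i * self.sh:i * self.sh + self.kh,
                   j * self.sw:j * self.sw + self.kw] += \
                    grad[:, :, i, j][:, :, None, None] * scale
        return dx


class MaxPool2d(Layer):
    def __init__(self, kernel: tuple[int, int], stride: tuple[int, int] | None = None):
        self.kh, self.kw = kernel
        self.sh, self.sw = stride if stride is not None else kernel
        self._cache = None

    def forward(self, x):
        v = np.lib.stride_tricks.sliding_window_view(x, (self.kh, self.kw),
                                                     axis=(2, 3))
        v = v[:, :, ::self.sh, ::self.sw]
        n, c, ho, wo = v.shape[:4]
        flat = v.reshape(n, c, ho, wo, self.kh * self.kw)
        arg = flat.argmax(axis=4)
        self._cache = (x.shape, arg)
        return np.take_along_axis(flat, arg[..., None], axis=4)[..., 0]

    def backward(self, grad):
        xshape, arg = self._cache
        dx = np.zeros(xshape, dtype=grad.dtype)
        ho, wo = grad.shape[2], grad.shape[3]
        ki, kj = np.divmod(arg, self.kw)
        n, c = xshape[0], xshape[1]
        ni, ci = np.meshgrid(np.arange(n), np.arange(c), indexing="ij")
        for i in range(ho):
            for j in range(wo):
                np.add.at(dx,
                          (ni, ci, i * self.sh + ki[:, :, i, j],
                           j * self.sw + kj[:, :, i, j]),
                          grad[:, :, i, j])
        return dx


class Dropout(Layer):
    def __init__(self, p: float, rng: np.random.Generator):
        if not 0 <= p < 1:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng
        self._mask = None

    def forward(self, x):
        if not self.training or self.p == 0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask.astype(x.dtype)

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask.astype(grad.dtype)


class Flatten(Layer):
    def __init__(self):
        self._shape = None

    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)
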