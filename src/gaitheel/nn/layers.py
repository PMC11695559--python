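"""A compact CPU neural-network engine on numpy.

Implements exactly the layer set the heel-keypoint architectures need:
(grouped) convolution, transposed convolution, batch normalization, ReLU /
ReLU6, max pooling, adaptive average pooling, dropout and linear layers,
each with a hand-written backward pass.  Arrays are NCHW float32 by default
(float64 is supported for finite-difference gradient checking).

Every layer caches what its backward pass needs during ``forward(...,
training=True)``; inference with ``training=False`` skips the caches,
batch statistics and dropout.
"""

from __future__ import annotations

import numpy as np

from .functional import (
    batchnorm_backward,
    batchnorm_forward,
    channel_sum_sumsq,
    col2im_add,
    conv_out_size,
    depthwise3x3_backward,
    depthwise3x3_forward,
    im2col,
)

__all__ = [
    "Param",
    "Module",
    "Sequential",
    "Conv2d",
    "ConvTranspose2d",
    "BatchNorm2d",
    "ReLU",
    "ReLU6",
    "MaxPool2d",
    "AdaptiveAvgPool2d",
    "Flatten",
    "Dropout",
    "Linear",
    "Residual",
]


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = ""):
        self.data = data
        self.grad = np.zeros_like(data)
        self.name = name

    @property
    def size(self) -> int:
        return self.data.size


class Module:
    """Base layer: ``forward(x, training)`` then ``backward(grad_out)``."""

    def parameters(self) -> list[Param]:
        out: list[Param] = []
        for v in vars(self).values():
            if isinstance(v, Param):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
        return out

    def buffers(self) -> list[np.ndarray]:
        out = []
        for v in vars(self).values():
            if isinstance(v, Module):
                out.extend(v.buffers())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.buffers())
        return out

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return self.forward(x, training)

    # -- state dict (flat arrays, save/load with np.savez) --

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()] + self.buffers()

    def load_state_arrays(self, arrays: list[np.ndarray]):
        targets = self.state_arrays()
        if len(arrays) != len(targets):
            raise ValueError(
                f"state has {len(arrays)} arrays, model needs {len(targets)}")
        for dst, src in zip(targets, arrays):
            if dst.shape != src.shape:
                raise ValueError(f"shape mismatch {dst.shape} vs {src.shape}")
            dst[...] = src


class Sequential(Module):
    def __init__(self, *modules: Module):
        self.modules = list(modules)

    def forward(self, x, training=False):
        for m in self.modules:
            x = m.forward(x, training)
        return x

    def backward(self, grad):
        for m in reversed(self.modules):
            grad = m.backward(grad)
        return grad


def _kaiming_normal(rng, shape, fan_in, dtype):
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


class Conv2d(Module):
    """(Grouped) 2D convolution, GEMM over im2col patches.

    Weight layout (out_channels, in_channels/groups, k, k); 1x1 unpadded
    convolutions bypass im2col entirely and run as plain channel GEMMs.
    """

    def __init__(self, in_channels, out_channels, kernel_size, stride=1,
                 padding=0, groups=1, bias=True, rng=None, dtype=np.float32):
        if in_channels % groups or out_channels % groups:
            raise ValueError("channels must be divisible by groups")
        rng = rng or np.random.default_rng(0)
        self.cin, self.cout = in_channels, out_channels
        self.k, self.stride, self.padding, self.groups = (
            kernel_size, stride, padding, groups)
        fan_in = (in_channels // groups) * kernel_size * kernel_size
        self.weight = Param(_kaiming_normal(
            rng, (out_channels, in_channels // groups, kernel_size, kernel_size),
            fan_in, dtype))
        self.bias = Param(np.zeros(out_channels, dtype=dtype)) if bias else None
        self._cache = None

    @property
    def _depthwise(self) -> bool:
        return (self.k == 3 and self.groups == self.cin
                and self.cin == self.cout)

    def forward(self, x, training=False):
        n, c, h, w = x.shape
        g = self.groups
        oh = conv_out_size(h, self.k, self.stride, self.padding)
        ow = conv_out_size(w, self.k, self.stride, self.padding)
        if self._depthwise:
            out, xp = depthwise3x3_forward(x, self.weight.data, self.stride,
                                           self.padding)
            if self.bias is not None:
                out += self.bias.data[None, :, None, None]
            if training:
                self._cache = (xp, x.shape)
            return out
        if self.k == 1 and self.padding == 0:
            xs = x[:, :, ::self.stride, ::self.stride] if self.stride > 1 else x
            cols = np.ascontiguousarray(xs).reshape(n, g, c // g, oh * ow)
        else:
            cols = im2col(x, self.k, self.stride, self.padding)
            cols = cols.reshape(n, g, (c // g) * self.k * self.k, oh * ow)
        wmat = self.weight.data.reshape(g, self.cout // g, -1)
        out = np.matmul(wmat[None], cols)          # (n, g, cout/g, L)
        out = out.reshape(n, self.cout, oh, ow)
        if self.bias is not None:
            out += self.bias.data[None, :, None, None]
        if training:
            self._cache = (cols, x.shape)
        return out

    def backward(self, grad):
        if self._depthwise:
            xp, x_shape = self._cache
            dx, dw = depthwise3x3_backward(xp, self.weight.data, grad,
                                           self.stride, self.padding, x_shape)
            self.weight.grad += dw
            if self.bias is not None:
                self.bias.grad += grad.sum(axis=(0, 2, 3))
            self._cache = None
            return dx
        cols, x_shape = self._cache
        n, c, h, w = x_shape
        g = self.groups
        gr = grad.reshape(n, g, self.cout // g, -1)
        wmat = self.weight.data.reshape(g, self.cout // g, -1)
        self.weight.grad += (
            np.matmul(gr, cols.transpose(0, 1, 3, 2)).sum(axis=0)
            .reshape(self.weight.data.shape))
        if self.bias is not None:
            self.bias.grad += grad.sum(axis=(0, 2, 3))
        dcols = np.matmul(wmat.transpose(0, 2, 1)[None], gr)
        if self.k == 1 and self.padding == 0:
            oh = conv_out_size(h, 1, self.stride, 0)
            ow = conv_out_size(w, 1, self.stride, 0)
            dx = np.zeros(x_shape, dtype=grad.dtype)
            dx[:, :, ::self.stride, ::self.stride] = dcols.reshape(n, c, oh, ow)
        else:
            dcols = dcols.reshape(n, c * self.k * self.k, -1)
            dx = col2im_add(dcols, x_shape, self.k, self.stride, self.padding)
        self._cache = None
        return dx


class ConvTranspose2d(Module):
    """Stride-s transposed convolution (fractionally strided upsampling).

    Forward is a GEMM producing patch columns scattered onto the output
    grid; backward gathers patches from the output gradient, so the pair
    reuses the same im2col/col2im kernels as `Conv2d`, swapped.
    """

    def __init__(self, in_channels, out_channels, kernel_size=4, stride=2,
                 padding=1, bias=False, rng=None, dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        self.cin, self.cout = in_channels, out_channels
        self.k, self.stride, self.padding = kernel_size, stride, padding
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = Param(_kaiming_normal(
            rng, (in_channels, out_channels, kernel_size, kernel_size),
            fan_in, dtype))
        self.bias = Param(np.zeros(out_channels, dtype=dtype)) if bias else None
        self._cache = None

    def out_size(self, size: int) -> int:
        return (size - 1) * self.stride - 2 * self.padding + self.k

    def forward(self, x, training=False):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h * w)
        wmat = self.weight.data.reshape(c, -1)     # (cin, cout*k*k)
        cols = np.matmul(wmat.T[None], xr)         # (n, cout*k*k, h*w)
        out = col2im_add(cols, (n, self.cout, self.out_size(h), self.out_size(w)),
                         self.k, self.stride, self.padding)
        if self.bias is not None:
            out += self.bias.data[None, :, None, None]
        if training:
            self._cache = (xr, (h, w))
        return out

    def backward(self, grad):
        xr, (h, w) = self._cache
        n = grad.shape[0]
        gcols = im2col(grad, self.k, self.stride, self.padding)  # (n, cout*k*k, h*w)
        wmat = self.weight.data.reshape(self.cin, -1)
        self.weight.grad += (
            np.matmul(xr, gcols.transpose(0, 2, 1)).sum(axis=0)
            .reshape(self.weight.data.shape))
        if self.bias is not None:
            self.bias.grad += grad.sum(axis=(0, 2, 3))
        dx = np.matmul(wmat[None], gcols).reshape(n, self.cin, h, w)
        self._cache = None
        return dx


class BatchNorm2d(Module):
    def __init__(self, channels, eps=1e-5, momentum=0.1, dtype=np.float32):
        self.eps, self.momentum = eps, momentum
        self.gamma = Param(np.ones(channels, dtype=dtype))
        self.beta = Param(np.zeros(channels, dtype=dtype))
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self._cache = None

    def buffers(self):
        return [self.running_mean, self.running_var]

    def forward(self, x, training=False):
        if training:
            m = x.shape[0] * x.shape[2] * x.shape[3]
            s, sq = channel_sum_sumsq(x)
            mean = (s / m).astype(x.dtype)
            var = np.maximum(sq / m - (s / m) ** 2, 0.0).astype(x.dtype)
            self.running_mean[...] = ((1 - self.momentum) * self.running_mean
                                      + self.momentum * mean)
            unbiased = var * (m / max(m - 1, 1))
            self.running_var[...] = ((1 - self.momentum) * self.running_var
                                     + self.momentum * unbiased)
            invstd = (1.0 / np.sqrt(var + self.eps)).astype(x.dtype)
            out, xhat = batchnorm_forward(x, mean, invstd, self.gamma.data,
                                          self.beta.data)
            self._cache = (xhat, invstd)
            return out
        mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * invstd[None, :, None, None]
        return (xhat * self.gamma.data[None, :, None, None]
                + self.beta.data[None, :, None, None])

    def backward(self, grad):
        xhat, invstd = self._cache
        dx, dgamma, dbeta = batchnorm_backward(grad, xhat, self.gamma.data,
                                               invstd)
        self.gamma.grad += dgamma
        self.beta.grad += dbeta
        self._cache = None
        return dx


class ReLU(Module):
    def forward(self, x, training=False):
        out = np.maximum(x, 0)
        if training:
            self._out = out
        return out

    def backward(self, grad):
        grad = grad * (self._out > 0)
        self._out = None
        return grad


class ReLU6(Module):
    def forward(self, x, training=False):
        out = np.clip(x, 0, 6)
        if training:
            self._x = x
        return out

    def backward(self, grad):
        grad = grad * ((self._x > 0) & (self._x < 6))
        self._x = None
        return grad


class MaxPool2d(Module):
    """Max pooling, floor mode; supports overlap (stride < kernel) and
    padding (padded positions never win the max)."""

    def __init__(self, kernel_size=2, stride=None, padding=0):
        self.k = kernel_size
        self.stride = stride if stride is not None else kernel_size
        self.padding = padding

    def forward(self, x, training=False):
        n, c, h, w = x.shape
        k, s, p = self.k, self.stride, self.padding
        if p:
            lowest = np.finfo(x.dtype).min
            xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)),
                        constant_values=lowest)
        else:
            xp = x
        cols = im2col(xp, k, s, 0).reshape(n, c, k * k, -1)
        idx = cols.argmax(axis=2)
        out_flat = np.take_along_axis(cols, idx[:, :, None, :], axis=2)[:, :, 0, :]
        oh = conv_out_size(h, k, s, p)
        ow = conv_out_size(w, k, s, p)
        out = out_flat.reshape(n, c, oh, ow)
        if training:
            self._cache = (idx, x.shape)
        return out

    def backward(self, grad):
        idx, x_shape = self._cache
        n, c, h, w = x_shape
        k, s, p = self.k, self.stride, self.padding
        gflat = grad.reshape(n, c, 1, -1)
        dcols = np.zeros((n, c, k * k, gflat.shape[-1]), dtype=grad.dtype)
        np.put_along_axis(dcols, idx[:, :, None, :], gflat, axis=2)
        dx = col2im_add(dcols.reshape(n, c * k * k, -1), x_shape, k, s, p)
        self._cache = None
        return dx


class AdaptiveAvgPool2d(Module):
    """Average pooling to a fixed output grid (same windowing rule as the
    common deep-learning frameworks: start floor(i*H/out), end ceil((i+1)*H/out))."""

    def __init__(self, output_size: tuple[int, int]):
        self.oh, self.ow = output_size

    def _bounds(self, size, out):
        starts = (np.arange(out) * size) // out
        ends = -(-(np.arange(1, out + 1) * size) // out)
        return starts, ends

    def forward(self, x, training=False):
        n, c, h, w = x.shape
        ys, ye = self._bounds(h, self.oh)
        xs, xe = self._bounds(w, self.ow)
        out = np.empty((n, c, self.oh, self.ow), dtype=x.dtype)
        for i in range(self.oh):
            for j in range(self.ow):
                out[:, :, i, j] = x[:, :, ys[i]:ye[i], xs[j]:xe[j]].mean(axis=(2, 3))
        if training:
            self._cache = x.shape
        return out

    def backward(self, grad):
        n, c, h, w = self._cache
        ys, ye = self._bounds(h, self.oh)
        xs, xe = self._bounds(w, self.ow)
        dx = np.zeros((n, c, h, w), dtype=grad.dtype)
        for i in range(self.oh):
            for j in range(self.ow):
                area = (ye[i] - ys[i]) * (xe[j] - xs[j])
                dx[:, :, ys[i]:ye[i], xs[j]:xe[j]] += (
                    grad[:, :, i, j][:, :, None, None] / area)
        self._cache = None
        return dx


class Flatten(Module):
    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dropout(Module):
    """Inverted dropout; identity at inference."""

    def __init__(self, p=0.5, rng=None):
        self.p = p
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x, training=False):
        if not training or self.p <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Linear(Module):
    def __init__(self, in_features, out_features, bias=True, rng=None,
                 dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        self.weight = Param(_kaiming_normal(
            rng, (out_features, in_features), in_features, dtype))
        self.bias = Param(np.zeros(out_features, dtype=dtype)) if bias else None
        self._x = None

    def forward(self, x, training=False):
        out = x @ self.weight.data.T
        if self.bias is not None:
            out += self.bias.data
        if training:
            self._x = x
        return out

    def backward(self, grad):
        self.weight.grad += grad.T @ self._x
        if self.bias is not None:
            self.bias.grad += grad.sum(axis=0)
        dx = grad @ self.weight.data
        self._x = None
        return dx


class Residual(Module):
    """``post(main(x) + shortcut(x))`` with identity shortcut when None."""

    def __init__(self, main: Module, shortcut: Module | None = None,
                 post: Module | None = None):
        self.main = main
        self.shortcut = shortcut
        self.post = post

    def forward(self, x, training=False):
        out = self.main.forward(x, training)
        out = out + (self.shortcut.forward(x, training)
                     if self.shortcut is not None else x)
        if self.post is not None:
            out = self.post.forward(out, training)
        return out

    def backward(self, grad):
        if self.post is not None:
            grad = self.post.backward(grad)
        dx = self.main.backward(grad)
        dx = dx + (self.shortcut.backward(grad)
                   if self.shortcut is not None else grad)
        return dx
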