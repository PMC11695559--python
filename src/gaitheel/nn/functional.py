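"""Array kernels behind the layer implementations.

Convolutions are expressed as GEMMs over im2col patch matrices (BLAS does
the heavy lifting); the scatter-add inverse (col2im) that backpropagation
and transposed convolution need is a compiled numba kernel, since numpy has
no efficient indexed accumulation.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from numpy.lib.stride_tricks import as_strided

__all__ = [
    "im2col", "col2im_add", "conv_out_size",
    "depthwise3x3_forward", "depthwise3x3_backward",
    "channel_sum_sumsq",
]


def conv_out_size(size: int, kernel: int, stride: int, padding: int) -> int:
    return (size + 2 * padding - kernel) // stride + 1


def im2col(x: np.ndarray, kernel: int, stride: int, padding: int) -> np.ndarray:
    """Patch matrix of ``x`` (N, C, H, W) -> (N, C*k*k, OH*OW)."""
    n, c, h, w = x.shape
    oh = conv_out_size(h, kernel, stride, padding)
    ow = conv_out_size(w, kernel, stride, padding)
    if padding:
        x = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    s0, s1, s2, s3 = x.strides
    view = as_strided(
        x,
        shape=(n, c, kernel, kernel, oh, ow),
        strides=(s0, s1, s2, s3, s2 * stride, s3 * stride),
    )
    return view.reshape(n, c * kernel * kernel, oh * ow)


@njit(cache=True)
def _col2im_kernel(cols, out, kernel, stride):  # pragma: no cover - numba
    n_b, _, _ = cols.shape
    c_ch = out.shape[1]
    hp, wp = out.shape[2], out.shape[3]
    oh = (hp - kernel) // stride + 1
    ow = (wp - kernel) // stride + 1
    for n in range(n_b):
        for c in range(c_ch):
            for ki in range(kernel):
                for kj in range(kernel):
                    row = (c * kernel + ki) * kernel + kj
                    for i in range(oh):
                        ih = i * stride + ki
                        base = i * ow
                        for j in range(ow):
                            out[n, c, ih, j * stride + kj] += cols[n, row, base + j]


def col2im_add(cols: np.ndarray, out_shape: tuple[int, int, int, int],
               kernel: int, stride: int, padding: int) -> np.ndarray:
    """Scatter-add patches (N, C*k*k, OH*OW) back onto an image grid,
    returning the (N, C, H, W) result with ``padding`` rows/cols removed."""
    n, c, h, w = out_shape
    hp, wp = h + 2 * padding, w + 2 * padding
    out = np.zeros((n, c, hp, wp), dtype=cols.dtype)
    _col2im_kernel(np.ascontiguousarray(cols), out, kernel, stride)
    if padding:
        out = out[:, :, padding:hp - padding, padding:wp - padding]
    return np.ascontiguousarray(out)


@njit(cache=True)
def _dw3x3_fwd(xp, w, stride, out):  # pragma: no cover - numba
    n_b, c_ch, hp, wp = xp.shape
    oh, ow = out.shape[2], out.shape[3]
    for n in range(n_b):
        for c in range(c_ch):
            for i in range(oh):
                ih = i * stride
                for j in range(ow):
                    jw = j * stride
                    acc = 0.0
                    for ki in range(3):
                        for kj in range(3):
                            acc += w[c, ki, kj] * xp[n, c, ih + ki, jw + kj]
                    out[n, c, i, j] = acc


@njit(cache=True)
def _dw3x3_bwd(xp, w, grad, stride, dxp, dw):  # pragma: no cover - numba
    n_b, c_ch, hp, wp = xp.shape
    oh, ow = grad.shape[2], grad.shape[3]
    for n in range(n_b):
        for c in range(c_ch):
            for i in range(oh):
                ih = i * stride
                for j in range(ow):
                    jw = j * stride
                    g = grad[n, c, i, j]
                    for ki in range(3):
                        for kj in range(3):
                            dxp[n, c, ih + ki, jw + kj] += w[c, ki, kj] * g
                            dw[c, ki, kj] += xp[n, c, ih + ki, jw + kj] * g


def depthwise3x3_forward(x: np.ndarray, weight: np.ndarray, stride: int,
                         padding: int) -> tuple[np.ndarray, np.ndarray]:
    """Depthwise 3x3 convolution; returns (output, padded input for reuse
    by the backward pass)."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding))) \
        if padding else x
    oh = conv_out_size(h, 3, stride, padding)
    ow = conv_out_size(w, 3, stride, padding)
    out = np.empty((n, c, oh, ow), dtype=x.dtype)
    _dw3x3_fwd(np.ascontiguousarray(xp), weight.reshape(c, 3, 3), stride, out)
    return out, xp


def depthwise3x3_backward(xp: np.ndarray, weight: np.ndarray,
                          grad: np.ndarray, stride: int, padding: int,
                          x_shape) -> tuple[np.ndarray, np.ndarray]:
    """Gradients (dx, dweight) of the depthwise 3x3 convolution."""
    c = x_shape[1]
    dxp = np.zeros_like(xp)
    dw = np.zeros((c, 3, 3), dtype=grad.dtype)
    _dw3x3_bwd(np.ascontiguousarray(xp), weight.reshape(c, 3, 3),
               np.ascontiguousarray(grad), stride, dxp, dw)
    if padding:
        dxp = np.ascontiguousarray(
            dxp[:, :, padding:-padding, padding:-padding])
    return dxp, dw.reshape(weight.shape)


@njit(cache=True)
def _chan_stats(xr, s, sq):  # pragma: no cover - numba
    n_b, c_ch, l = xr.shape
    for n in range(n_b):
        for c in range(c_ch):
            acc = 0.0
            acc2 = 0.0
            for i in range(l):
                v = xr[n, c, i]
                acc += v
                acc2 += v * v
            s[c] += acc
            sq[c] += acc2


def channel_sum_sumsq(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel sum and sum of squares of an NCHW batch, one pass."""
    n, c = x.shape[:2]
    xr = np.ascontiguousarray(x).reshape(n, c, -1)
    s = np.zeros(c, dtype=np.float64)
    sq = np.zeros(c, dtype=np.float64)
    _chan_stats(xr, s, sq)
    return s, sq


@njit(cache=True)
def _bn_fwd(xr, mean, invstd, gamma, beta, out, xhat):  # pragma: no cover
    n_b, c_ch, l = xr.shape
    for n in range(n_b):
        for c in range(c_ch):
            mu = mean[c]
            s = invstd[c]
            g = gamma[c]
            b = beta[c]
            for i in range(l):
                h = (xr[n, c, i] - mu) * s
                xhat[n, c, i] = h
                out[n, c, i] = g * h + b


@njit(cache=True)
def _bn_bwd(gr, xhat, gamma, invstd, dgamma, dbeta, dx):  # pragma: no cover
    n_b, c_ch, l = gr.shape
    m = n_b * l
    for c in range(c_ch):
        sg = 0.0
        sb = 0.0
        for n in range(n_b):
            for i in range(l):
                g = gr[n, c, i]
                sg += g * xhat[n, c, i]
                sb += g
        dgamma[c] += sg
        dbeta[c] += sb
        k = gamma[c] * invstd[c] / m
        for n in range(n_b):
            for i in range(l):
                dx[n, c, i] = k * (m * gr[n, c, i] - sb
                                   - xhat[n, c, i] * sg)


def batchnorm_forward(x, mean, invstd, gamma, beta):
    """Fused (x - mean) * invstd * gamma + beta; returns (out, xhat)."""
    n, c = x.shape[:2]
    xr = np.ascontiguousarray(x).reshape(n, c, -1)
    out = np.empty_like(xr)
    xhat = np.empty_like(xr)
    _bn_fwd(xr, mean.astype(x.dtype), invstd.astype(x.dtype),
            gamma.astype(x.dtype), beta.astype(x.dtype), out, xhat)
    return out.reshape(x.shape), xhat


def batchnorm_backward(grad, xhat, gamma, invstd):
    """Fused batch-norm input/parameter gradients.

    Returns (dx, dgamma, dbeta); xhat is the flattened cache from forward.
    """
    n, c = grad.shape[:2]
    gr = np.ascontiguousarray(grad).reshape(n, c, -1)
    dgamma = np.zeros(c, dtype=grad.dtype)
    dbeta = np.zeros(c, dtype=grad.dtype)
    dx = np.empty_like(gr)
    _bn_bwd(gr, xhat, gamma.astype(grad.dtype), invstd.astype(grad.dtype),
            dgamma, dbeta, dx)
    return dx.reshape(grad.shape), dgamma, dbeta
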