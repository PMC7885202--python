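"""Minimal differentiable tensor operations on NCHW arrays.

Conventions:

* feature maps are ``(batch, channels, height, width)`` arrays;
* all spatial ops use "same" padding: output size is ``ceil(size / stride)``;
* batch normalization always uses the statistics of the current batch
  (no running averages) — search and evaluation both operate on
  mini-batches, which keeps the computation purely functional.

The heavy ops (convolutions, pooling, batch norm) are registered as autograd
primitives with hand-written vector-Jacobian products: the autodiff tape then
stores only their inputs and outputs, and the backward pass recomputes cheap
intermediates.  Slower autograd-traced reference implementations
(``conv2d_ref`` etc.) are kept for testing the hand-written gradients.
"""

from __future__ import annotations

import autograd.numpy as anp
import numpy as np
from autograd.extend import defvjp, primitive
from autograd.scipy.special import logsumexp

from . import _kernels as _k

__all__ = [
    "same_padding",
    "conv_output_shape",
    "conv2d",
    "depthwise_conv2d",
    "max_pool2d",
    "avg_pool2d",
    "batch_norm",
    "relu",
    "global_avg_pool",
    "linear",
    "softmax",
    "cross_entropy",
]

BN_EPS = 1e-5


def same_padding(size: int, kernel: int, stride: int, dilation: int = 1):
    """Return ``(out_size, pad_before, pad_after)`` for same-padding."""
    if size <= 0:
        raise ValueError(f"spatial size must be positive, got {size}")
    k_eff = dilation * (kernel - 1) + 1
    out = -(-size // stride)  # ceil division
    pad = max((out - 1) * stride + k_eff - size, 0)
    return out, pad // 2, pad - pad // 2


def conv_output_shape(h: int, w: int, stride: int):
    """Spatial shape contract shared by every primitive: ceil(size/stride)."""
    return -(-h // stride), -(-w // stride)


def _geometry(shape, kh, kw, stride, dilation):
    """Padded-input geometry shared by forward and backward passes."""
    n, c, h, w = shape
    sh, sw = (stride, stride) if np.isscalar(stride) else stride
    ho, ph0, ph1 = same_padding(h, kh, sh, dilation)
    wo, pw0, pw1 = same_padding(w, kw, sw, dilation)
    return (sh, sw, ho, wo, ph0, ph1, pw0, pw1)


def _pad(x, ph0, ph1, pw0, pw1, value=0.0):
    return np.pad(
        x, ((0, 0), (0, 0), (ph0, ph1), (pw0, pw1)),
        mode="constant", constant_values=value,
    )


def _view(xp, i, j, sh, sw, ho, wo, dilation):
    """Strided view of the padded input for kernel offset (i, j)."""
    r0, c0 = i * dilation, j * dilation
    return xp[:, :, r0 : r0 + (ho - 1) * sh + 1 : sh, c0 : c0 + (wo - 1) * sw + 1 : sw]


# ---------------------------------------------------------------------------
# convolutions
# ---------------------------------------------------------------------------


@primitive
def conv2d(x, weight, stride=1, dilation=1):
    """Full convolution with same-padding; ``weight`` is (c_out, c_in, kh, kw)."""
    c_out, c_in, kh, kw = weight.shape
    if x.shape[1] != c_in:
        raise ValueError(f"expected {c_in} input channels, got {x.shape[1]}")
    sh, sw, ho, wo, ph0, ph1, pw0, pw1 = _geometry(x.shape, kh, kw, stride, dilation)
    n = x.shape[0]
    if kh == kw == 1 and sh == sw == 1:  # pointwise fast path: one batched matmul
        out = np.matmul(weight[:, :, 0, 0], np.ascontiguousarray(x).reshape(n, c_in, -1))
        return out.reshape(n, c_out, ho, wo)
    xp = _pad(x, ph0, ph1, pw0, pw1)
    out = np.zeros((n, c_out, ho * wo), dtype=np.result_type(x, weight))
    for i in range(kh):
        for j in range(kw):
            v = np.ascontiguousarray(_view(xp, i, j, sh, sw, ho, wo, dilation))
            out += np.matmul(weight[:, :, i, j], v.reshape(n, c_in, ho * wo))
    return out.reshape(n, c_out, ho, wo)


def _conv2d_vjp_x(ans, x, weight, stride=1, dilation=1):
    c_out, c_in, kh, kw = weight.shape
    sh, sw, ho, wo, ph0, ph1, pw0, pw1 = _geometry(x.shape, kh, kw, stride, dilation)

    def vjp(g):
        n = x.shape[0]
        gr = np.ascontiguousarray(g).reshape(n, c_out, ho * wo)
        if kh == kw == 1 and sh == sw == 1:
            return np.matmul(weight[:, :, 0, 0].T, gr).reshape(x.shape)
        gxp = np.zeros(
            (n, c_in, x.shape[2] + ph0 + ph1, x.shape[3] + pw0 + pw1), dtype=g.dtype
        )
        for i in range(kh):
            for j in range(kw):
                contrib = np.matmul(weight[:, :, i, j].T, gr).reshape(n, c_in, ho, wo)
                _view(gxp, i, j, sh, sw, ho, wo, dilation)[...] += contrib
        return gxp[:, :, ph0 : ph0 + x.shape[2], pw0 : pw0 + x.shape[3]]

    return vjp


def _conv2d_vjp_w(ans, x, weight, stride=1, dilation=1):
    c_out, c_in, kh, kw = weight.shape
    sh, sw, ho, wo, ph0, ph1, pw0, pw1 = _geometry(x.shape, kh, kw, stride, dilation)

    def vjp(g):
        n = x.shape[0]
        gr = np.ascontiguousarray(g).reshape(n, c_out, ho * wo)
        if kh == kw == 1 and sh == sw == 1:
            xr = np.ascontiguousarray(x).reshape(n, c_in, ho * wo)
            gw = np.matmul(gr, xr.transpose(0, 2, 1)).sum(axis=0)
            return gw[:, :, None, None]
        xp = _pad(x, ph0, ph1, pw0, pw1)
        gw = np.empty_like(weight, dtype=g.dtype)
        for i in range(kh):
            for j in range(kw):
                v = np.ascontiguousarray(_view(xp, i, j, sh, sw, ho, wo, dilation))
                gw[:, :, i, j] = np.matmul(
                    gr, v.reshape(n, c_in, ho * wo).transpose(0, 2, 1)
                ).sum(axis=0)
        return gw

    return vjp


defvjp(conv2d, _conv2d_vjp_x, _conv2d_vjp_w)


@primitive
def depthwise_conv2d(x, weight, stride=1, dilation=1):
    """Per-channel convolution with same-padding; ``weight`` is (c, kh, kw)."""
    c, kh, kw = weight.shape
    if x.shape[1] != c:
        raise ValueError(f"expected {c} input channels, got {x.shape[1]}")
    sh, sw, ho, wo, ph0, ph1, pw0, pw1 = _geometry(x.shape, kh, kw, stride, dilation)
    xp = _pad(x, ph0, ph1, pw0, pw1)
    return _k.dw_fwd(xp, np.ascontiguousarray(weight), sh, sw, ho, wo, dilation)


def _depthwise_vjp_x(ans, x, weight, stride=1, dilation=1):
    c, kh, kw = weight.shape
    sh, sw, ho, wo, ph0, ph1, pw0, pw1 = _geometry(x.shape, kh, kw, stride, dilation)

    def vjp(g):
        gxp = _k.dw_bwd_x(
            np.ascontiguousarray(g), np.ascontiguousarray(weight), x.shape[0], c,
            x.shape[2] + ph0 + ph1, x.shape[3] + pw0 + pw1, sh, sw, dilation,
        )
        return gxp[:, :, ph0 : ph0 + x.shape[2], pw0 : pw0 + x.shape[3]]

    return vjp


def _depthwise_vjp_w(ans, x, weight, stride=1, dilation=1):
    c, kh, kw = weight.shape
    sh, sw, ho, wo, ph0, ph1, pw0, pw1 = _geometry(x.shape, kh, kw, stride, dilation)

    def vjp(g):
        xp = _pad(x, ph0, ph1, pw0, pw1)
        return _k.dw_bwd_w(np.ascontiguousarray(g), xp, kh, kw, sh, sw, dilation)

    return vjp


defvjp(depthwise_conv2d, _depthwise_vjp_x, _depthwise_vjp_w)


# ---------------------------------------------------------------------------
# pooling
# ---------------------------------------------------------------------------


@primitive
def max_pool2d(x, kernel=3, stride=1):
    sh, sw, ho, wo, ph0, ph1, pw0, pw1 = _geometry(x.shape, kernel, kernel, stride, 1)
    xp = _pad(x, ph0, ph1, pw0, pw1, value=-np.inf)
    return _k.maxpool_fwd(xp, kernel, sh, sw, ho, wo)


def _max_pool_vjp(ans, x, kernel=3, stride=1):
    sh, sw, ho, wo, ph0, ph1, pw0, pw1 = _geometry(x.shape, kernel, kernel, stride, 1)

    def vjp(g):
        xp = _pad(x, ph0, ph1, pw0, pw1, value=-np.inf)
        gxp = _k.maxpool_bwd(xp, ans, np.ascontiguousarray(g), kernel, sh, sw)
        return gxp[:, :, ph0 : ph0 + x.shape[2], pw0 : pw0 + x.shape[3]]

    return vjp


defvjp(max_pool2d, _max_pool_vjp)


def _pool_counts(shape, kernel, stride):
    """Number of non-padded cells per pooling window (constant)."""
    ones = np.ones((1, 1, shape[2], shape[3]))
    sh, sw, ho, wo, ph0, ph1, pw0, pw1 = _geometry(ones.shape, kernel, kernel, stride, 1)
    op = _pad(ones, ph0, ph1, pw0, pw1)
    counts = np.zeros((1, 1, ho, wo))
    for i in range(kernel):
        for j in range(kernel):
            counts += _view(op, i, j, sh, sw, ho, wo, 1)
    return counts


@primitive
def avg_pool2d(x, kernel=3, stride=1):
    """Average pooling; padded cells are excluded from the mean."""
    sh, sw, ho, wo, ph0, ph1, pw0, pw1 = _geometry(x.shape, kernel, kernel, stride, 1)
    xp = _pad(x, ph0, ph1, pw0, pw1)
    out = np.zeros((x.shape[0], x.shape[1], ho, wo), dtype=x.dtype)
    for i in range(kernel):
        for j in range(kernel):
            out += _view(xp, i, j, sh, sw, ho, wo, 1)
    return out / _pool_counts(x.shape, kernel, stride).astype(x.dtype)


def _avg_pool_vjp(ans, x, kernel=3, stride=1):
    sh, sw, ho, wo, ph0, ph1, pw0, pw1 = _geometry(x.shape, kernel, kernel, stride, 1)

    def vjp(g):
        gd = g / _pool_counts(x.shape, kernel, stride).astype(g.dtype)
        gxp = np.zeros(
            (x.shape[0], x.shape[1], x.shape[2] + ph0 + ph1, x.shape[3] + pw0 + pw1),
            dtype=g.dtype,
        )
        for i in range(kernel):
            for j in range(kernel):
                _view(gxp, i, j, sh, sw, ho, wo, 1)[...] += gd
        return gxp[:, :, ph0 : ph0 + x.shape[2], pw0 : pw0 + x.shape[3]]

    return vjp


defvjp(avg_pool2d, _avg_pool_vjp)


# ---------------------------------------------------------------------------
# batch normalization
# ---------------------------------------------------------------------------


def _bn_stats(x, eps):
    mu = x.mean(axis=(0, 2, 3), keepdims=True)
    var = np.mean((x - mu) ** 2, axis=(0, 2, 3), keepdims=True)
    return mu, 1.0 / np.sqrt(var + eps)


@primitive
def _bn(x, gamma, beta, eps=BN_EPS):
    mu, inv_std = _bn_stats(x, eps)
    return gamma.reshape(1, -1, 1, 1) * ((x - mu) * inv_std) + beta.reshape(1, -1, 1, 1)


def _bn_vjp_x(ans, x, gamma, beta, eps=BN_EPS):
    def vjp(g):
        mu, inv_std = _bn_stats(x, eps)
        z = (x - mu) * inv_std
        dz = g * gamma.reshape(1, -1, 1, 1)
        m = x.shape[0] * x.shape[2] * x.shape[3]
        s1 = dz.sum(axis=(0, 2, 3), keepdims=True)
        s2 = (dz * z).sum(axis=(0, 2, 3), keepdims=True)
        return (inv_std / m) * (m * dz - s1 - z * s2)

    return vjp


def _bn_vjp_gamma(ans, x, gamma, beta, eps=BN_EPS):
    def vjp(g):
        mu, inv_std = _bn_stats(x, eps)
        return np.sum(g * (x - mu) * inv_std, axis=(0, 2, 3))

    return vjp


def _bn_vjp_beta(ans, x, gamma, beta, eps=BN_EPS):
    return lambda g: np.sum(g, axis=(0, 2, 3))


defvjp(_bn, _bn_vjp_x, _bn_vjp_gamma, _bn_vjp_beta)


def batch_norm(x, gamma=None, beta=None, eps=BN_EPS):
    """Normalize each channel by batch statistics; affine transform optional."""
    if gamma is None:
        c = x.shape[1]
        gamma = np.ones(c, dtype=np.result_type(x.dtype, np.float32))
        beta = np.zeros(c, dtype=gamma.dtype)
    return _bn(x, gamma, beta, eps=eps)


# ---------------------------------------------------------------------------
# small traced ops
# ---------------------------------------------------------------------------


def relu(x):
    return anp.maximum(x, 0.0)


def global_avg_pool(x):
    """(n, c, h, w) -> (n, c)."""
    return anp.mean(x, axis=(2, 3))


def linear(x, weight, bias):
    """(n, f) @ (out, f).T + (out,)."""
    return anp.dot(x, weight.T) + bias


def softmax(z, axis=-1):
    z = z - anp.max(z, axis=axis, keepdims=True)
    e = anp.exp(z)
    return e / anp.sum(e, axis=axis, keepdims=True)


def cross_entropy(logits, labels):
    """Mean negative log-likelihood of integer ``labels`` under ``logits``."""
    n = logits.shape[0]
    log_z = logsumexp(logits, axis=1)
    ll = logits[anp.arange(n), labels] - log_z
    return -anp.mean(ll)


# ---------------------------------------------------------------------------
# traced reference implementations (test oracles for the manual gradients)
# ---------------------------------------------------------------------------


def _patches_ref(x, kh, kw, stride, dilation=1, pad_value=0.0):
    n, c, h, w = x.shape
    sh, sw = (stride, stride) if np.isscalar(stride) else stride
    ho, ph0, ph1 = same_padding(h, kh, sh, dilation)
    wo, pw0, pw1 = same_padding(w, kw, sw, dilation)
    xp = anp.pad(
        x, ((0, 0), (0, 0), (ph0, ph1), (pw0, pw1)),
        mode="constant", constant_values=pad_value,
    )
    cols = []
    for i in range(kh):
        for j in range(kw):
            r0, c0 = i * dilation, j * dilation
            cols.append(xp[:, :, r0 : r0 + (ho - 1) * sh + 1 : sh, c0 : c0 + (wo - 1) * sw + 1 : sw])
    return anp.stack(cols), ho, wo


def conv2d_ref(x, weight, stride=1, dilation=1):
    c_out, c_in, kh, kw = weight.shape
    patches, _, _ = _patches_ref(x, kh, kw, stride, dilation)
    wm = anp.reshape(weight, (c_out, c_in, kh * kw))
    return anp.moveaxis(anp.tensordot(wm, patches, axes=((1, 2), (2, 0))), 0, 1)


def depthwise_conv2d_ref(x, weight, stride=1, dilation=1):
    c, kh, kw = weight.shape
    patches, _, _ = _patches_ref(x, kh, kw, stride, dilation)
    return anp.einsum("ck,knchw->nchw", anp.reshape(weight, (c, kh * kw)), patches)


def max_pool2d_ref(x, kernel=3, stride=1):
    patches, _, _ = _patches_ref(x, kernel, kernel, stride, pad_value=-np.inf)
    return anp.max(patches, axis=0)


def avg_pool2d_ref(x, kernel=3, stride=1):
    patches, _, _ = _patches_ref(x, kernel, kernel, stride, pad_value=0.0)
    return anp.sum(patches, axis=0) / _pool_counts(x.shape, kernel, stride)


def batch_norm_ref(x, gamma=None, beta=None, eps=BN_EPS):
    mu = anp.mean(x, axis=(0, 2, 3), keepdims=True)
    var = anp.mean((x - mu) ** 2, axis=(0, 2, 3), keepdims=True)
    z = (x - mu) / anp.sqrt(var + eps)
    if gamma is not None:
        z = anp.reshape(gamma, (1, -1, 1, 1)) * z + anp.reshape(beta, (1, -1, 1, 1))
    return z
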