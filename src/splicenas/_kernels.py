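"""Numba JIT kernels for the depthwise-convolution and max-pooling loops.

Full convolutions are BLAS-bound and handled in :mod:`splicenas.nnops` with
batched ``matmul``; the per-channel (depthwise) and pooling loops have no
efficient BLAS mapping at these tiny spatial sizes, so they are JIT-compiled
here.  All kernels operate on the already-padded input ``xp``; geometry
(strides, dilation, output size) is resolved by the caller.  ``fastmath``
stays off so results are bit-reproducible across runs.
"""

from __future__ import annotations

import numba as nb
import numpy as np

_JIT = dict(cache=True, fastmath=False, nogil=True)


@nb.njit(**_JIT)
def dw_fwd(xp, w, sh, sw, ho, wo, dil):
    n, c, hp, wp = xp.shape
    kh, kw = w.shape[1], w.shape[2]
    out = np.zeros((n, c, ho, wo), dtype=xp.dtype)
    xf = xp.reshape(n, c, hp * wp)
    of = out.reshape(n, c, ho * wo)
    for b in range(n):
        for ch in range(c):
            xc = xf[b, ch]
            oc = of[b, ch]
            for i in range(kh):
                for j in range(kw):
                    wv = w[ch, i, j]
                    jd = j * dil
                    for y in range(ho):
                        base = (y * sh + i * dil) * wp + jd
                        ob = y * wo
                        for x in range(wo):
                            oc[ob + x] += wv * xc[base + x * sw]
    return out


@nb.njit(**_JIT)
def dw_bwd_x(g, w, n, c, hp, wp, sh, sw, dil):
    kh, kw = w.shape[1], w.shape[2]
    ho, wo = g.shape[2], g.shape[3]
    gxp = np.zeros((n, c, hp * wp), dtype=g.dtype)
    gf = g.reshape(n, c, ho * wo)
    for b in range(n):
        for ch in range(c):
            gc = gf[b, ch]
            oc = gxp[b, ch]
            for i in range(kh):
                for j in range(kw):
                    wv = w[ch, i, j]
                    jd = j * dil
                    for y in range(ho):
                        base = (y * sh + i * dil) * wp + jd
                        gb = y * wo
                        for x in range(wo):
                            oc[base + x * sw] += wv * gc[gb + x]
    return gxp.reshape(n, c, hp, wp)


@nb.njit(**_JIT)
def dw_bwd_w(g, xp, kh, kw, sh, sw, dil):
    n, c, ho, wo = g.shape
    hp, wp = xp.shape[2], xp.shape[3]
    gw = np.zeros((c, kh, kw), dtype=g.dtype)
    gf = g.reshape(n, c, ho * wo)
    xf = xp.reshape(n, c, hp * wp)
    for b in range(n):
        for ch in range(c):
            gc = gf[b, ch]
            xc = xf[b, ch]
            for i in range(kh):
                for j in range(kw):
                    jd = j * dil
                    acc = np.float64(0.0)
                    for y in range(ho):
                        base = (y * sh + i * dil) * wp + jd
                        gb = y * wo
                        for x in range(wo):
                            acc += gc[gb + x] * xc[base + x * sw]
                    gw[ch, i, j] += acc
    return gw


@nb.njit(**_JIT)
def maxpool_fwd(xp, k, sh, sw, ho, wo):
    n, c = xp.shape[0], xp.shape[1]
    out = np.empty((n, c, ho, wo), dtype=xp.dtype)
    for b in range(n):
        for ch in range(c):
            xc = xp[b, ch]
            oc = out[b, ch]
            for y in range(ho):
                for x in range(wo):
                    m = xc[y * sh, x * sw]
                    for i in range(k):
                        xr = xc[y * sh + i]
                        for j in range(k):
                            v = xr[x * sw + j]
                            if v > m:
                                m = v
                    oc[y, x] = m
    return out


@nb.njit(**_JIT)
def maxpool_bwd(xp, ans, g, k, sh, sw):
    """Route each window's gradient to the first occurrence of its maximum."""
    n, c, ho, wo = ans.shape
    gxp = np.zeros(xp.shape, dtype=g.dtype)
    for b in range(n):
        for ch in range(c):
            xc = xp[b, ch]
            gc = gxp[b, ch]
            for y in range(ho):
                for x in range(wo):
                    target = ans[b, ch, y, x]
                    done = False
                    for i in range(k):
                        if done:
                            break
                        xr = xc[y * sh + i]
                        for j in range(k):
                            if xr[x * sw + j] == target:
                                gc[y * sh + i, x * sw + j] += g[b, ch, y, x]
                                done = True
                                break
    return gxp
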