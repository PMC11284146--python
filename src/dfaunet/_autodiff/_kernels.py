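"""Optional compiled kernels for operations that are overhead-bound in NumPy.

Dense convolutions run through im2col + BLAS and stay in NumPy.  Depthwise
convolutions and the GELU non-linearity, however, spend most of their time in
Python-level looping or temporary allocation; when numba is importable they
are lowered to single-pass compiled loops.  Every caller keeps a pure-NumPy
fallback, so the package works (more slowly) without numba.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - exercised only without numba
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(fn):
            return fn

        if args and callable(args[0]):
            return args[0]
        return deco


@njit(cache=True)
def dw_conv_fwd(xp, w):
    """Depthwise stride-1 conv; ``xp`` is the padded (N,C,Hp,Wp) input,
    ``w`` is (C, kh, kw).  Returns (N, C, Ho, Wo)."""
    n, c, ph, pw = xp.shape
    kh, kw = w.shape[1], w.shape[2]
    ho, wo = ph - kh + 1, pw - kw + 1
    out = np.zeros((n, c, ho, wo), dtype=xp.dtype)
    for nn in range(n):
        for cc in range(c):
            for i in range(kh):
                for j in range(kw):
                    wv = w[cc, i, j]
                    for y in range(ho):
                        for x in range(wo):
                            out[nn, cc, y, x] += wv * xp[nn, cc, y + i, x + j]
    return out


@njit(cache=True)
def dw_conv_bwd(xp, w, g):
    """Gradients of :func:`dw_conv_fwd` w.r.t. padded input and weight."""
    n, c, ph, pw = xp.shape
    kh, kw = w.shape[1], w.shape[2]
    ho, wo = g.shape[2], g.shape[3]
    gxp = np.zeros_like(xp)
    gw = np.zeros_like(w)
    for nn in range(n):
        for cc in range(c):
            for i in range(kh):
                for j in range(kw):
                    wv = w[cc, i, j]
                    acc = 0.0
                    for y in range(ho):
                        for x in range(wo):
                            gv = g[nn, cc, y, x]
                            gxp[nn, cc, y + i, x + j] += wv * gv
                            acc += gv * xp[nn, cc, y + i, x + j]
                    gw[cc, i, j] += acc
    return gxp, gw


@njit(cache=True)
def gelu_fwd(x):
    """Tanh-approximation GELU, single pass; returns (out, tanh-term)."""
    flat = x.ravel()
    out = np.empty_like(flat)
    t = np.empty_like(flat)
    c = np.float64(0.7978845608028654)  # sqrt(2/pi)
    a = 0.044715
    for i in range(flat.size):
        v = flat[i]
        ti = np.tanh(c * (v + a * v * v * v))
        t[i] = ti
        out[i] = 0.5 * v * (1.0 + ti)
    return out.reshape(x.shape), t.reshape(x.shape)


@njit(cache=True)
def leaky_fwd(x, slope):
    flat = x.ravel()
    out = np.empty_like(flat)
    for i in range(flat.size):
        v = flat[i]
        out[i] = v if v > 0 else slope * v
    return out.reshape(x.shape)


@njit(cache=True)
def leaky_bwd(x, g, slope):
    xf, gf = x.ravel(), g.ravel()
    gx = np.empty_like(gf)
    for i in range(xf.size):
        gx[i] = gf[i] if xf[i] > 0 else slope * gf[i]
    return gx.reshape(x.shape)


@njit(cache=True)
def scale_shift(x, a, b):
    """Per-channel affine ``x * a[c] + b[c]`` on an (N, C, H, W) map."""
    n, c, h, w = x.shape
    out = np.empty_like(x)
    for nn in range(n):
        for cc in range(c):
            av, bv = a[cc], b[cc]
            for y in range(h):
                for xx in range(w):
                    out[nn, cc, y, xx] = x[nn, cc, y, xx] * av + bv
    return out


@njit(cache=True)
def bn_bwd_train(x, g, mu, inv, w):
    """Training-mode batch-norm input/affine gradients in two fused passes."""
    n, c, h, wd = x.shape
    m = n * h * wd
    gx = np.empty_like(x)
    gw = np.zeros(c, dtype=x.dtype)
    gb = np.zeros(c, dtype=x.dtype)
    for cc in range(c):
        s1 = 0.0
        s2 = 0.0
        for nn in range(n):
            for y in range(h):
                for xx in range(wd):
                    gv = g[nn, cc, y, xx]
                    xh = (x[nn, cc, y, xx] - mu[cc]) * inv[cc]
                    s1 += gv
                    s2 += gv * xh
        gb[cc] = s1
        gw[cc] = s2
        m1 = w[cc] * s1 / m
        m2 = w[cc] * s2 / m
        for nn in range(n):
            for y in range(h):
                for xx in range(wd):
                    xh = (x[nn, cc, y, xx] - mu[cc]) * inv[cc]
                    gx[nn, cc, y, xx] = inv[cc] * (
                        g[nn, cc, y, xx] * w[cc] - m1 - xh * m2
                    )
    return gx, gw, gb


@njit(cache=True)
def gelu_bwd(x, t, g):
    flat, tf, gf = x.ravel(), t.ravel(), g.ravel()
    gx = np.empty_like(flat)
    c = np.float64(0.7978845608028654)
    a = 0.044715
    for i in range(flat.size):
        v = flat[i]
        ti = tf[i]
        dt = (1.0 - ti * ti) * c * (1.0 + 3.0 * a * v * v)
        gx[i] = gf[i] * (0.5 * (1.0 + ti) + 0.5 * v * dt)
    return gx.reshape(x.shape)
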