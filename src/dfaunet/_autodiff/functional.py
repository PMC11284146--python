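"""Neural-network operations with fused forward/backward rules.

All spatial operations use the (N, C, H, W) layout.  Convolutions are
evaluated by im2col + matrix multiplication so the heavy lifting happens in
BLAS; the column-to-image scatter in the backward pass loops only over the
kernel footprint (at most 7x7 here).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from . import _kernels
from .tensor import Tensor

__all__ = [
    "conv2d",
    "conv_transpose2d",
    "max_pool2d",
    "bilinear_resize",
    "softmax",
    "sigmoid",
    "relu",
    "leaky_relu",
    "gelu",
    "layer_norm_channels",
    "batch_norm",
]


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int):
    """(N, C, H, W) -> contiguous (N, C*kh*kw, Ho*Wo) columns plus (Ho, Wo).

    Channel-first column layout: a plain matmul with the (Cout, C*kh*kw)
    weight matrix then yields NCHW output directly, with no transposes on
    either side of the GEMM.
    """
    v = sliding_window_view(x, (kh, kw), axis=(2, 3))  # N C Ho' Wo' kh kw
    v = v[:, :, ::stride, ::stride]
    n, c, ho, wo = v.shape[:4]
    cols = np.ascontiguousarray(v.transpose(0, 1, 4, 5, 2, 3))
    return cols.reshape(n, c * kh * kw, ho * wo), (ho, wo)


def _col2im(cols: np.ndarray, shape, kh, kw, stride, ho, wo):
    """Adjoint of :func:`_im2col`; cols is (N, C*kh*kw, Ho*Wo)."""
    n, c, h, w = shape
    cols = cols.reshape(n, c, kh, kw, ho, wo)
    out = np.zeros(shape, dtype=cols.dtype)
    for i in range(kh):
        for j in range(kw):
            out[:, :, i : i + ho * stride : stride, j : j + wo * stride : stride] += (
                cols[:, :, i, j]
            )
    return out


def _conv_input_grad_s1(g: np.ndarray, weight: np.ndarray, padding):
    """Input gradient of a stride-1 conv as a correlation with the flipped kernel.

    Avoids the scatter-add of col2im: the gradient w.r.t. the (padded) input is
    itself a stride-1 convolution of the zero-padded output gradient with the
    spatially flipped, in/out-transposed weight, so it runs through BLAS.
    """
    cout, cin, kh, kw = weight.shape
    n = g.shape[0]
    gp = np.pad(g, ((0, 0), (0, 0), (kh - 1, kh - 1), (kw - 1, kw - 1)))
    cols, (ph, pw) = _im2col(gp, kh, kw, 1)
    wf = weight[:, :, ::-1, ::-1].transpose(1, 0, 2, 3).reshape(cin, cout * kh * kw)
    gxp = np.matmul(wf, cols).reshape(n, cin, ph, pw)
    if padding:
        gxp = gxp[:, :, padding:-padding or None, padding:-padding or None]
    return gxp


def conv2d(
    x: Tensor,
    weight: Tensor,
    bias: Tensor | None = None,
    stride: int = 1,
    padding: int = 0,
    groups: int = 1,
) -> Tensor:
    """2-D cross-correlation.  ``weight`` is (Cout, Cin/groups, kh, kw)."""
    cout, cin_g, kh, kw = weight.shape
    n, cin, h, w = x.shape
    if cin % groups or cout % groups:
        raise ValueError(f"groups={groups} must divide Cin={cin} and Cout={cout}")
    xd = x.data
    if padding:
        xd = np.pad(xd, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    ph, pw = xd.shape[2], xd.shape[3]
    ho = (ph - kh) // stride + 1
    wo = (pw - kw) // stride + 1

    if kh == 1 and kw == 1 and stride == 1 and groups == 1:
        # pointwise conv: a channel-mixing matmul, no im2col copy needed
        wmat = weight.data.reshape(cout, cin)
        out = np.matmul(wmat, xd.reshape(n, cin, ph * pw)).reshape(n, cout, ph, pw)
        if bias is not None:
            out += bias.data[None, :, None, None]
        needs = x.requires_grad or weight.requires_grad or (
            bias is not None and bias.requires_grad
        )
        if not needs:
            return Tensor(out)

        def bw_pw(g):
            g2 = g.reshape(n, cout, ph * pw)
            if weight.requires_grad:
                xr = xd.reshape(n, cin, ph * pw)
                gw = np.matmul(g2, xr.transpose(0, 2, 1)).sum(axis=0)
                weight._accumulate(gw.reshape(weight.shape))
            if x.requires_grad:
                gx = np.matmul(wmat.T, g2).reshape(n, cin, ph, pw)
                x._accumulate(gx)
            if bias is not None and bias.requires_grad:
                bias._accumulate(g.sum(axis=(0, 2, 3)))

        parents = (x, weight) + ((bias,) if bias is not None else ())
        return Tensor(out, True, parents, bw_pw)

    if groups == 1:
        cols, _ = _im2col(xd, kh, kw, stride)  # N, Cin*kh*kw, Ho*Wo
        wmat = weight.data.reshape(cout, cin * kh * kw)
        out = np.matmul(wmat, cols).reshape(n, cout, ho, wo)
    elif groups == cin and cout == cin:
        # depthwise: one filter per channel.  Small maps go through a single
        # windowed einsum (per-call overhead dominates there); large maps are
        # accumulated tap by tap over the kernel footprint (strided views, no
        # window materialisation).
        if stride != 1:
            raise NotImplementedError("depthwise conv implemented for stride 1 only")
        wd = weight.data
        if _kernels.HAVE_NUMBA:
            out = _kernels.dw_conv_fwd(xd, wd[:, 0])
        elif ho * wo <= 1024:
            v = sliding_window_view(xd, (kh, kw), axis=(2, 3))
            out = np.einsum("nchwij,cij->nchw", v, wd[:, 0], optimize=True)
        else:
            out = np.zeros((n, cin, ho, wo), dtype=xd.dtype)
            for i in range(kh):
                for j in range(kw):
                    out += (
                        xd[:, :, i : i + ho, j : j + wo]
                        * wd[None, :, 0, i, j, None, None]
                    )
        cols = xd  # keep padded input for the weight gradient
    else:
        # general grouped conv (rarely needed): loop over groups
        outs, cols_g = [], []
        cg_in, cg_out = cin // groups, cout // groups
        for g in range(groups):
            xg = xd[:, g * cg_in : (g + 1) * cg_in]
            cg, _ = _im2col(xg, kh, kw, stride)
            cols_g.append(cg)
            wg = weight.data[g * cg_out : (g + 1) * cg_out].reshape(cg_out, -1)
            outs.append(np.matmul(wg, cg).reshape(n, cg_out, ho, wo))
        out = np.concatenate(outs, axis=1)
        cols = cols_g

    if bias is not None:
        out += bias.data[None, :, None, None]

    needs = x.requires_grad or weight.requires_grad or (
        bias is not None and bias.requires_grad
    )
    if not needs:
        return Tensor(out)

    padded_shape = (n, cin, ph, pw)

    def bw(g):
        g3 = g.reshape(n, cout, ho * wo)
        if groups == 1:
            if weight.requires_grad:
                gw = np.matmul(g3, cols.transpose(0, 2, 1)).sum(axis=0)
                weight._accumulate(gw.reshape(weight.shape))
            if x.requires_grad:
                if stride == 1:
                    gx = _conv_input_grad_s1(g, weight.data, padding)
                else:
                    gcols = np.matmul(weight.data.reshape(cout, -1).T, g3)
                    gx = _col2im(gcols, padded_shape, kh, kw, stride, ho, wo)
                    if padding:
                        gx = gx[
                            :, :, padding:-padding or None, padding:-padding or None
                        ]
                x._accumulate(gx)
        elif groups == cin and cout == cin:
            if _kernels.HAVE_NUMBA:
                gc = np.ascontiguousarray(g, dtype=cols.dtype)
                gxp, gw = _kernels.dw_conv_bwd(cols, weight.data[:, 0], gc)
                if weight.requires_grad:
                    weight._accumulate(gw[:, None])
                if x.requires_grad:
                    if padding:
                        gxp = gxp[
                            :, :, padding:-padding or None, padding:-padding or None
                        ]
                    x._accumulate(gxp)
            else:
                if weight.requires_grad:
                    if ho * wo <= 1024:
                        v = sliding_window_view(cols, (kh, kw), axis=(2, 3))
                        gw = np.einsum("nchwij,nchw->cij", v, g, optimize=True)
                        weight._accumulate(gw[:, None])
                    else:
                        gw = np.empty((cin, 1, kh, kw), dtype=g.dtype)
                        for i in range(kh):
                            for j in range(kw):
                                gw[:, 0, i, j] = np.einsum(
                                    "nchw,nchw->c",
                                    cols[:, :, i : i + ho, j : j + wo], g,
                                    optimize=True,
                                )
                        weight._accumulate(gw)
                if x.requires_grad:
                    wd = weight.data
                    gxp = np.zeros(padded_shape, dtype=g.dtype)
                    for i in range(kh):
                        for j in range(kw):
                            gxp[:, :, i : i + ho, j : j + wo] += (
                                g * wd[None, :, 0, i, j, None, None]
                            )
                    if padding:
                        gxp = gxp[
                            :, :, padding:-padding or None, padding:-padding or None
                        ]
                    x._accumulate(gxp)
        else:
            cg_in, cg_out = cin // groups, cout // groups
            gx_full = np.zeros(padded_shape, dtype=g.dtype) if x.requires_grad else None
            gw_full = np.zeros(weight.shape, dtype=g.dtype) if weight.requires_grad else None
            for gi in range(groups):
                gg = g3[:, gi * cg_out : (gi + 1) * cg_out]
                cg = cols[gi]
                wg = weight.data[gi * cg_out : (gi + 1) * cg_out].reshape(cg_out, -1)
                if gw_full is not None:
                    gw_full[gi * cg_out : (gi + 1) * cg_out] = (
                        np.matmul(gg, cg.transpose(0, 2, 1)).sum(axis=0)
                    ).reshape(cg_out, cg_in, kh, kw)
                if gx_full is not None:
                    gc = np.matmul(wg.T, gg)
                    gx_full[:, gi * cg_in : (gi + 1) * cg_in] += _col2im(
                        gc, (n, cg_in, ph, pw), kh, kw, stride, ho, wo
                    )
            if gw_full is not None:
                weight._accumulate(gw_full)
            if gx_full is not None:
                if padding:
                    gx_full = gx_full[
                        :, :, padding:-padding or None, padding:-padding or None
                    ]
                x._accumulate(gx_full)
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))

    parents = (x, weight) + ((bias,) if bias is not None else ())
    return Tensor(out, True, parents, bw)


def conv_transpose2d(x: Tensor, weight: Tensor, bias: Tensor | None = None, stride: int = 2) -> Tensor:
    """Transposed conv with kernel == stride (non-overlapping upsampling).

    ``weight`` is (Cin, Cout, k, k); output is (N, Cout, H*k, W*k).
    """
    cin, cout, k, _ = weight.shape
    if stride != k:
        raise NotImplementedError("only kernel == stride is supported")
    n, _, h, w = x.shape
    y = np.einsum("nchw,cdij->ndhiwj", x.data, weight.data, optimize=True)
    out = y.reshape(n, cout, h * k, w * k)
    if bias is not None:
        out += bias.data[None, :, None, None]

    needs = x.requires_grad or weight.requires_grad or (
        bias is not None and bias.requires_grad
    )
    if not needs:
        return Tensor(out)

    def bw(g):
        gr = g.reshape(n, cout, h, k, w, k)
        if x.requires_grad:
            x._accumulate(np.einsum("ndhiwj,cdij->nchw", gr, weight.data, optimize=True))
        if weight.requires_grad:
            weight._accumulate(
                np.einsum("ndhiwj,nchw->cdij", gr, x.data, optimize=True)
            )
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))

    parents = (x, weight) + ((bias,) if bias is not None else ())
    return Tensor(out, True, parents, bw)


def max_pool2d(x: Tensor, k: int = 2) -> Tensor:
    n, c, h, w = x.shape
    if h % k or w % k:
        raise ValueError(f"spatial size ({h},{w}) not divisible by pool {k}")
    xr = x.data.reshape(n, c, h // k, k, w // k, k).transpose(0, 1, 2, 4, 3, 5)
    xr = xr.reshape(n, c, h // k, w // k, k * k)
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    if not x.requires_grad:
        return Tensor(out)

    def bw(g):
        gcols = np.zeros((n, c, h // k, w // k, k * k), dtype=g.dtype)
        np.put_along_axis(gcols, idx[..., None], g[..., None], axis=-1)
        gx = (
            gcols.reshape(n, c, h // k, w // k, k, k)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h, w)
        )
        x._accumulate(gx)

    return Tensor(out, True, (x,), bw)


@lru_cache(maxsize=128)
def _resize_matrix(n_in: int, n_out: int, dtype_str: str) -> np.ndarray:
    """Bilinear interpolation matrix (n_out x n_in), half-pixel-center convention."""
    a = np.zeros((n_out, n_in), dtype=np.dtype(dtype_str))
    if n_in == 1:
        a[:, 0] = 1.0
        return a
    src = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
    src = np.clip(src, 0, n_in - 1)
    i0 = np.floor(src).astype(int)
    i1 = np.minimum(i0 + 1, n_in - 1)
    frac = src - i0
    a[np.arange(n_out), i0] += 1 - frac
    a[np.arange(n_out), i1] += frac
    return a


def bilinear_resize(x: Tensor, size: tuple[int, int]) -> Tensor:
    """Resize (N, C, H, W) to (N, C, *size) by bilinear interpolation."""
    n, c, h, w = x.shape
    ho, wo = size
    if (ho, wo) == (h, w):
        return x * 1.0 if x.requires_grad else Tensor(x.data.copy())
    ah = _resize_matrix(h, ho, str(x.dtype))
    aw = _resize_matrix(w, wo, str(x.dtype))
    out = np.matmul(ah, np.matmul(x.data, aw.T))

    if not x.requires_grad:
        return Tensor(out)

    def bw(g):
        x._accumulate(np.matmul(ah.T, np.matmul(g, aw)))

    return Tensor(out, True, (x,), bw)


# ---------------------------------------------------------------------------
# activations / normalisation
# ---------------------------------------------------------------------------

def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    out = e / e.sum(axis=axis, keepdims=True)

    if not x.requires_grad:
        return Tensor(out)

    def bw(g):
        inner = (g * out).sum(axis=axis, keepdims=True)
        x._accumulate(out * (g - inner))

    return Tensor(out, True, (x,), bw)


def sigmoid(x: Tensor) -> Tensor:
    out = 1.0 / (1.0 + np.exp(-x.data))

    if not x.requires_grad:
        return Tensor(out)

    def bw(g):
        x._accumulate(g * out * (1 - out))

    return Tensor(out, True, (x,), bw)


def relu(x: Tensor) -> Tensor:
    return leaky_relu(x, 0.0)


def leaky_relu(x: Tensor, negative_slope: float = 0.01) -> Tensor:
    xd = x.data
    if _kernels.HAVE_NUMBA:
        xd = np.ascontiguousarray(xd)
        out = _kernels.leaky_fwd(xd, xd.dtype.type(negative_slope))
    else:
        out = np.where(xd > 0, xd, negative_slope * xd)

    if not x.requires_grad:
        return Tensor(out)

    def bw(g):
        if _kernels.HAVE_NUMBA:
            gx = _kernels.leaky_bwd(
                xd, np.ascontiguousarray(g), xd.dtype.type(negative_slope)
            )
        else:
            gx = np.where(xd > 0, g, negative_slope * g)
        x._accumulate(gx)

    return Tensor(out, True, (x,), bw)


def gelu(x: Tensor) -> Tensor:
    """Gaussian error linear unit (tanh approximation)."""
    xd = x.data
    c = xd.dtype.type(np.sqrt(2.0 / np.pi))  # keep dtype: avoid float64 upcasts
    x2 = xd * xd  # x**3 via np.power is orders of magnitude slower than multiplies
    inner = c * (xd + 0.044715 * (x2 * xd))
    t = np.tanh(inner)
    out = 0.5 * xd * (1 + t)

    if not x.requires_grad:
        return Tensor(out)

    def bw(g):
        if _kernels.HAVE_NUMBA:
            x._accumulate(_kernels.gelu_bwd(xd, t, np.ascontiguousarray(g)))
            return
        dt = (1 - t * t) * c * (1 + 3 * 0.044715 * x2)
        x._accumulate(g * (0.5 * (1 + t) + 0.5 * xd * dt))

    return Tensor(out, True, (x,), bw)


def layer_norm_channels(x: Tensor, weight: Tensor, bias: Tensor, eps: float = 1e-6) -> Tensor:
    """LayerNorm over the channel axis of an (N, C, H, W) map."""
    mu = x.data.mean(axis=1, keepdims=True)
    xc = x.data - mu
    var = (xc**2).mean(axis=1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out = weight.data[None, :, None, None] * xhat + bias.data[None, :, None, None]

    needs = x.requires_grad or weight.requires_grad or bias.requires_grad
    if not needs:
        return Tensor(out)

    c = x.shape[1]

    def bw(g):
        if weight.requires_grad:
            weight._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        if bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gh = g * weight.data[None, :, None, None]
            m1 = gh.mean(axis=1, keepdims=True)
            m2 = (gh * xhat).mean(axis=1, keepdims=True)
            x._accumulate(inv * (gh - m1 - xhat * m2))

    return Tensor(out, True, (x, weight, bias), bw)


def batch_norm(
    x: Tensor,
    weight: Tensor,
    bias: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Batch normalisation over (N, H, W) per channel; mutates running stats."""
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
        running_mean *= 1 - momentum
        running_mean += momentum * mu
        running_var *= 1 - momentum
        running_var += momentum * var * (m / max(m - 1, 1))  # unbiased for stats
    else:
        mu, var = running_mean, running_var
    inv = (1.0 / np.sqrt(var + eps)).astype(x.data.dtype)
    mu = mu.astype(x.data.dtype)
    use_kernel = _kernels.HAVE_NUMBA and x.data.ndim == 4
    if use_kernel:
        xd = np.ascontiguousarray(x.data)
        a = weight.data * inv
        out = _kernels.scale_shift(xd, a, bias.data - mu * a)
        xhat = None
    else:
        xd = x.data
        xhat = (xd - mu[None, :, None, None]) * inv[None, :, None, None]
        out = weight.data[None, :, None, None] * xhat + bias.data[None, :, None, None]

    needs = x.requires_grad or weight.requires_grad or bias.requires_grad
    if not needs:
        return Tensor(out)

    def bw(g):
        if use_kernel and training and x.requires_grad:
            gx, gw, gb = _kernels.bn_bwd_train(
                xd, np.ascontiguousarray(g), mu, inv, weight.data
            )
            if weight.requires_grad:
                weight._accumulate(gw)
            if bias.requires_grad:
                bias._accumulate(gb)
            x._accumulate(gx)
            return
        xh = (
            xhat
            if xhat is not None
            else (xd - mu[None, :, None, None]) * inv[None, :, None, None]
        )
        if weight.requires_grad:
            weight._accumulate((g * xh).sum(axis=(0, 2, 3)))
        if bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gh = g * weight.data[None, :, None, None]
            if training:
                m1 = gh.mean(axis=(0, 2, 3), keepdims=True)
                m2 = (gh * xh).mean(axis=(0, 2, 3), keepdims=True)
                x._accumulate(inv[None, :, None, None] * (gh - m1 - xh * m2))
            else:
                x._accumulate(gh * inv[None, :, None, None])

    return Tensor(out, True, (x, weight, bias), bw)
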