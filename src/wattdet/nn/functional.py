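"""Array-level neural-network primitives with autograd support."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = ["conv2d", "max_pool2d", "upsample_nearest2x", "conv2d_macs"]


def conv2d_macs(n, c_in, c_out, k, h_out, w_out, groups=1) -> int:
    """Multiply-accumulate count of one convolution forward pass."""
    return int(n * c_out * h_out * w_out * (c_in // groups) * k * k)


def _im2col(xp: np.ndarray, kh: int, kw: int, sh: int, sw: int) -> np.ndarray:
    """(N,C,Hp,Wp) -> (N,C,kh,kw,Ho,Wo) view-based patch extraction."""
    v = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    v = v[:, :, ::sh, ::sw]                      # N,C,Ho,Wo,kh,kw
    return np.ascontiguousarray(v.transpose(0, 1, 4, 5, 2, 3))


def _col2im(cols: np.ndarray, shape: tuple, sh: int, sw: int) -> np.ndarray:
    """Inverse of :func:`_im2col` with overlap accumulation."""
    n, c, kh, kw, ho, wo = cols.shape
    x = np.zeros(shape, dtype=np.float32)
    for i in range(kh):
        for j in range(kw):
            x[:, :, i:i + sh * ho:sh, j:j + sw * wo:sw] += cols[:, :, i, j]
    return x


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1,
           padding: int = 0, groups: int = 1) -> Tensor:
    """2-D cross-correlation, NCHW layout, square stride/padding."""
    n, c, h, wdt = x.shape
    co, cpg, kh, kw = w.shape
    if c != cpg * groups:
        raise ValueError(f"channel mismatch: input {c}, weight expects {cpg * groups}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding))) \
        if padding else x.data
    ho = (xp.shape[2] - kh) // stride + 1
    wo = (xp.shape[3] - kw) // stride + 1
    cols = _im2col(xp, kh, kw, stride, stride)   # N,C,kh,kw,Ho,Wo
    ck = cpg * kh * kw
    cols_m = cols.reshape(n, groups, ck, ho * wo)
    w_m = w.data.reshape(groups, co // groups, ck)
    out = np.matmul(w_m[None], cols_m).reshape(n, co, ho, wo)
    if b is not None:
        out += b.data.reshape(1, co, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def bw(out_t):
        def fn():
            go = out_t.grad.reshape(n, groups, co // groups, ho * wo)
            if b is not None and b.requires_grad:
                b._accum(out_t.grad.sum(axis=(0, 2, 3)))
            if w.requires_grad:
                gw = np.matmul(go, cols_m.transpose(0, 1, 3, 2)).sum(axis=0)
                w._accum(gw.reshape(w.shape))
            if x.requires_grad:
                gcols = np.matmul(w_m.transpose(0, 2, 1)[None], go)
                gcols = gcols.reshape(n, c, kh, kw, ho, wo)
                gx = _col2im(gcols, xp.shape, stride, stride)
                if padding:
                    gx = gx[:, :, padding:padding + h, padding:padding + wdt]
                x._accum(gx)
        return fn

    return Tensor._make(out, parents, bw)


def max_pool2d(x: Tensor, k: int, stride: int = 1, padding: int = 0) -> Tensor:
    xp = x.data
    if padding:
        xp = np.pad(xp, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                    constant_values=-np.inf)
    n, c, hp, wp = xp.shape
    v = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    v = v[:, :, ::stride, ::stride]              # N,C,Ho,Wo,k,k
    ho, wo = v.shape[2], v.shape[3]
    flat = v.reshape(n, c, ho, wo, k * k)
    arg = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

    def bw(out_t):
        def fn():
            if not x.requires_grad:
                return
            gxp = np.zeros((n, c, hp, wp), dtype=np.float32)
            ki, kj = np.divmod(arg, k)
            ii = (np.arange(ho) * stride)[None, None, :, None] + ki
            jj = (np.arange(wo) * stride)[None, None, None, :] + kj
            nn_, cc = np.meshgrid(np.arange(n), np.arange(c), indexing="ij")
            np.add.at(gxp, (nn_[..., None, None], cc[..., None, None], ii, jj),
                      out_t.grad)
            if padding:
                gxp = gxp[:, :, padding:hp - padding, padding:wp - padding]
            x._accum(gxp)
        return fn

    return Tensor._make(out, (x,), bw)


def upsample_nearest2x(x: Tensor) -> Tensor:
    n, c, h, w = x.shape
    out = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def bw(out_t):
        def fn():
            if x.requires_grad:
                g = out_t.grad.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5))
                x._accum(g)
        return fn

    return Tensor._make(out, (x,), bw)
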