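"""Building blocks of the nano-scale anchor-free detector.

Layer arithmetic (channel widths, bottleneck expansion ratios, attention
head sizing) mirrors the published nano reference design so that the
parameter and FLOP budgets are reproduced exactly.
"""

from __future__ import annotations

import math

import numpy as np

from . import nn
from .errors import ConfigurationError
from .wavelet import WTConv, WTConvSpec

__all__ = [
    "ConvBnAct", "DWConv", "Bottleneck", "C3k", "C3k2", "SPPF", "C2PSA",
    "Detect", "make_anchors",
]


class ConvBnAct(nn.Module):
    """Conv2d (no bias) + BatchNorm + SiLU; the workhorse layer."""

    def __init__(self, c1, c2, k=1, s=1, p=None, g=1, act=True):
        super().__init__()
        self.conv = nn.Conv2d(c1, c2, k, s, k // 2 if p is None else p,
                              groups=g, bias=False)
        self.bn = nn.BatchNorm2d(c2)
        self.act = act

    def forward(self, x):
        out = self.bn(self.conv(x))
        return out.silu() if self.act else out


class DWConv(ConvBnAct):
    def __init__(self, c1, c2, k=1, s=1, act=True):
        super().__init__(c1, c2, k, s, g=math.gcd(c1, c2), act=act)


class WTConvBnAct(nn.Module):
    """Drop-in for a square 3x3 ConvBnAct using wavelet-domain processing."""

    def __init__(self, c, k=3, levels=1):
        super().__init__()
        self.wt = WTConv(WTConvSpec(c, c, kernel_size=k, levels=levels))
        self.bn = nn.BatchNorm2d(c)

    def forward(self, x):
        return self.bn(self.wt(x)).silu()


#: Per-bottleneck modification: (cv1_kind, cv2_kind, attention_gate);
#: kinds are "conv" (standard 3x3) or "wt" (wavelet-domain); when a gate
#: is present cv2 collapses to a 1x1 convolution followed by the gate.
_PLAIN = ("conv", "conv", None)


class Bottleneck(nn.Module):
    """Two-conv residual bottleneck with per-conv modification hooks."""

    def __init__(self, c1, c2, shortcut=True, k=(3, 3), e=0.5,
                 plan=_PLAIN, wt_kernel=3, wt_levels=1):
        super().__init__()
        c_ = int(c2 * e)
        cv1_kind, cv2_kind, gate = plan
        if cv1_kind == "wt":
            if c1 != c_:
                raise ConfigurationError(
                    "wavelet convolution needs equal in/out channels")
            self.cv1 = WTConvBnAct(c_, wt_kernel, wt_levels)
        else:
            self.cv1 = ConvBnAct(c1, c_, k[0], 1)
        if gate is not None:
            self.cv2 = ConvBnAct(c_, c2, 1, 1)
        elif cv2_kind == "wt":
            if c_ != c2:
                raise ConfigurationError(
                    "wavelet convolution needs equal in/out channels")
            self.cv2 = WTConvBnAct(c2, wt_kernel, wt_levels)
        else:
            self.cv2 = ConvBnAct(c_, c2, k[1], 1)
        self.gate = gate
        self.add = shortcut and c1 == c2

    def forward(self, x):
        out = self.cv2(self.cv1(x))
        if self.gate is not None:
            out = self.gate(out)
        return x + out if self.add else out


class C3k(nn.Module):
    """CSP block with two serial bottlenecks (kernel-k variant)."""

    def __init__(self, c1, c2, n=2, shortcut=True, e=0.5,
                 plans=None, wt_kernel=3, wt_levels=1):
        super().__init__()
        c_ = int(c2 * e)
        plans = plans or [_PLAIN] * n
        self.cv1 = ConvBnAct(c1, c_, 1, 1)
        self.cv2 = ConvBnAct(c1, c_, 1, 1)
        self.cv3 = ConvBnAct(2 * c_, c2, 1)
        self.m = nn.Sequential(*(
            Bottleneck(c_, c_, shortcut, k=(3, 3), e=1.0, plan=plans[i],
                       wt_kernel=wt_kernel, wt_levels=wt_levels)
            for i in range(n)))

    def forward(self, x):
        return self.cv3(nn.cat([self.m(self.cv1(x)), self.cv2(x)], axis=1))


class C3k2(nn.Module):
    """Fast CSP stage: split, run n inner blocks, concatenate everything.

    ``site_plan`` maps a flattened bottleneck index to its modification
    triple; with ``c3k=True`` the two serial bottlenecks of the inner
    block have indices 0 and 1.
    """

    def __init__(self, c1, c2, n=1, c3k=False, e=0.5, shortcut=True,
                 site_plan=None, wt_kernel=3, wt_levels=1):
        super().__init__()
        self.c = int(c2 * e)
        self.cv1 = ConvBnAct(c1, 2 * self.c, 1, 1)
        self.cv2 = ConvBnAct((2 + n) * self.c, c2, 1)
        site_plan = site_plan or {}
        mods = []
        for i in range(n):
            if c3k:
                plans = [site_plan.get(2 * i + j, _PLAIN) for j in range(2)]
                mods.append(C3k(self.c, self.c, 2, shortcut, plans=plans,
                                wt_kernel=wt_kernel, wt_levels=wt_levels))
            else:
                mods.append(Bottleneck(self.c, self.c, shortcut, e=0.5,
                                       plan=site_plan.get(i, _PLAIN),
                                       wt_kernel=wt_kernel,
                                       wt_levels=wt_levels))
        self.m = nn.ModuleList(mods)

    def forward(self, x):
        y = self.cv1(x)
        a = y[:, : self.c]
        b = y[:, self.c:]
        outs = [a, b]
        for m in self.m:
            outs.append(m(outs[-1]))
        return self.cv2(nn.cat(outs, axis=1))


class SPPF(nn.Module):
    """Spatial pyramid pooling (fast): three chained k x k max pools."""

    def __init__(self, c1, c2, k=5):
        super().__init__()
        c_ = c1 // 2
        self.cv1 = ConvBnAct(c1, c_, 1, 1)
        self.cv2 = ConvBnAct(c_ * 4, c2, 1, 1)
        self.k = k

    def forward(self, x):
        y = [self.cv1(x)]
        for _ in range(3):
            y.append(nn.max_pool2d(y[-1], self.k, 1, self.k // 2))
        return self.cv2(nn.cat(y, axis=1))


class _PSAAttention(nn.Module):
    def __init__(self, dim, num_heads, attn_ratio=0.5):
        super().__init__()
        self.num_heads = num_heads
        self.head_dim = dim // num_heads
        self.key_dim = int(self.head_dim * attn_ratio)
        self.scale = self.key_dim ** -0.5
        h = dim + self.key_dim * num_heads * 2
        self.qkv = ConvBnAct(dim, h, 1, act=False)
        self.proj = ConvBnAct(dim, dim, 1, act=False)
        self.pe = ConvBnAct(dim, dim, 3, 1, g=dim, act=False)

    def forward(self, x):
        b, c, hh, ww = x.shape
        n = hh * ww
        qkv = self.qkv(x).reshape(
            b, self.num_heads, self.key_dim * 2 + self.head_dim, n)
        q = qkv[:, :, : self.key_dim]
        k = qkv[:, :, self.key_dim: 2 * self.key_dim]
        v = qkv[:, :, 2 * self.key_dim:]
        attn = (q.transpose(0, 1, 3, 2) @ k) * self.scale
        attn = attn.softmax(axis=-1)
        out = (v @ attn.transpose(0, 1, 3, 2)).reshape(b, c, hh, ww)
        out = out + self.pe(v.reshape(b, c, hh, ww))
        return self.proj(out)


class _PSABlock(nn.Module):
    def __init__(self, c, num_heads):
        super().__init__()
        self.attn = _PSAAttention(c, num_heads)
        self.ffn = nn.Sequential(ConvBnAct(c, c * 2, 1),
                                 ConvBnAct(c * 2, c, 1, act=False))

    def forward(self, x):
        x = x + self.attn(x)
        return x + self.ffn(x)


class C2PSA(nn.Module):
    """Partial self-attention stage at the backbone's deepest scale."""

    def __init__(self, c, n=1, e=0.5):
        super().__init__()
        self.c = int(c * e)
        self.cv1 = ConvBnAct(c, 2 * self.c, 1, 1)
        self.cv2 = ConvBnAct(2 * self.c, c, 1)
        self.m = nn.Sequential(*(
            _PSABlock(self.c, num_heads=self.c // 64) for _ in range(n)))

    def forward(self, x):
        y = self.cv1(x)
        a = y[:, : self.c]
        b = self.m(y[:, self.c:])
        return self.cv2(nn.cat([a, b], axis=1))


def make_anchors(shapes: list[tuple[int, int]], strides: list[int],
                 offset: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Per-location anchor centre points (in pixels) and stride vector."""
    pts, strs = [], []
    for (h, w), s in zip(shapes, strides):
        ys, xs = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        p = np.stack([(xs.ravel() + offset) * s, (ys.ravel() + offset) * s],
                     axis=1)
        pts.append(p)
        strs.append(np.full((h * w, 1), s, dtype=np.float64))
    return np.concatenate(pts).astype(np.float64), np.concatenate(strs)


class Detect(nn.Module):
    """Decoupled anchor-free head with distribution-focal box regression."""

    def __init__(self, nc=6, ch=(64, 128, 256), reg_max=16):
        super().__init__()
        self.nc = nc
        self.reg_max = reg_max
        self.strides = (8, 16, 32)
        c2 = max(16, ch[0] // 4, reg_max * 4)
        c3 = max(ch[0], min(nc, 100))
        self.cv2 = nn.ModuleList(
            nn.Sequential(ConvBnAct(x, c2, 3), ConvBnAct(c2, c2, 3),
                          nn.Conv2d(c2, 4 * reg_max, 1, bias=True))
            for x in ch)
        self.cv3 = nn.ModuleList(
            nn.Sequential(
                nn.Sequential(DWConv(x, x, 3), ConvBnAct(x, c3, 1)),
                nn.Sequential(DWConv(c3, c3, 3), ConvBnAct(c3, c3, 1)),
                nn.Conv2d(c3, nc, 1, bias=True))
            for x in ch)

    def bias_init(self):
        """Prior-probability initialization of the head output biases."""
        for i, s in enumerate(self.strides):
            self.cv2[i][-1].bias.data[:] = 1.0
            self.cv3[i][-1].bias.data[:] = float(
                np.log(5 / self.nc / (640 / s) ** 2))
        return self

    def forward(self, feats: list[nn.Tensor]) -> list[nn.Tensor]:
        """Raw per-scale maps: (N, 4*reg_max + nc, H, W)."""
        return [nn.cat([self.cv2[i](f), self.cv3[i](f)], axis=1)
                for i, f in enumerate(feats)]

    def decode(self, raw: list[nn.Tensor]) -> tuple[np.ndarray, np.ndarray]:
        """Decode raw maps to (boxes_xyxy_pixels, class_scores).

        Returns arrays of shape (N, A, 4) and (N, A, nc) where A is the
        total number of candidate locations.
        """
        shapes = [(r.shape[2], r.shape[3]) for r in raw]
        anchors, strides = make_anchors(shapes, list(self.strides))
        flat = [r.data.reshape(r.shape[0], r.shape[1], -1) for r in raw]
        cat = np.concatenate(flat, axis=2)               # N, C, A
        n = cat.shape[0]
        box = cat[:, : 4 * self.reg_max].reshape(n, 4, self.reg_max, -1)
        cls = cat[:, 4 * self.reg_max:]
        # distribution-focal expectation over reg_max bins
        z = box - box.max(axis=2, keepdims=True)
        e = np.exp(z)
        prob = e / e.sum(axis=2, keepdims=True)
        dist = (prob * np.arange(self.reg_max).reshape(1, 1, -1, 1)).sum(axis=2)
        dist = dist.transpose(0, 2, 1)                   # N, A, 4 (l,t,r,b)
        xy = anchors[None]
        x1y1 = xy - dist[:, :, :2] * strides[None]
        x2y2 = xy + dist[:, :, 2:] * strides[None]
        boxes = np.concatenate([x1y1, x2y2], axis=2)
        from scipy.special import expit
        scores = expit(cls.transpose(0, 2, 1))
        return boxes, scores
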