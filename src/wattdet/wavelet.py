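"""2-D discrete wavelet transform, its inverse, and the WTConv layer.

The transform follows the separable filter-bank convention: the analysis
filters run along the width axis first, then along the height axis, both
with stride 2.  Sub-band naming is fixed as

* ``L``    — low-pass along both axes,
* ``H_LH`` — high-pass along width, low-pass along height,
* ``H_HL`` — high-pass along height, low-pass along width,
* ``H_HH`` — high-pass along both axes.

Odd spatial sizes are reflect-padded to even before decomposition and
cropped after reconstruction.  For orthonormal families on even sizes the
transform is energy preserving and exactly invertible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .errors import ConfigurationError, DimensionError

__all__ = [
    "WAVELET_FAMILIES", "WaveletSubbands", "WTConvSpec",
    "dwt2d", "iwt2d", "WTConv", "wtconv_forward",
]

_SQRT2 = np.sqrt(2.0)

#: Analysis filters (low-pass, high-pass) of the supported orthonormal
#: families.  High-pass follows the forward-difference sign convention
#: (first tap positive), e.g. Haar high-pass is (x0 - x1)/sqrt(2).
WAVELET_FAMILIES: dict[str, tuple[np.ndarray, np.ndarray]] = {}


def _register(name: str, low: list[float]):
    low_a = np.asarray(low, dtype=np.float64)
    # quadrature mirror: g[k] = (-1)^k h[L-1-k]; sign flipped so the first
    # tap is positive (matches the documented Haar convention)
    high = np.array([((-1) ** k) * low_a[len(low_a) - 1 - k]
                     for k in range(len(low_a))])
    if high[np.argmax(np.abs(high) > 1e-12)] < 0:
        high = -high
    WAVELET_FAMILIES[name] = (low_a, high)


_register("haar", [1 / _SQRT2, 1 / _SQRT2])
_s3 = np.sqrt(3.0)
_register("db2", [(1 + _s3) / (4 * _SQRT2), (3 + _s3) / (4 * _SQRT2),
                  (3 - _s3) / (4 * _SQRT2), (1 - _s3) / (4 * _SQRT2)])


@dataclass
class WaveletSubbands:
    """One level of a 2-D wavelet decomposition of a ``C x H x W`` map."""

    L: np.ndarray
    H_LH: np.ndarray
    H_HL: np.ndarray
    H_HH: np.ndarray
    level: int = 1
    orig_shape: tuple[int, int] | None = None

    def __post_init__(self):
        shapes = {self.L.shape, self.H_LH.shape, self.H_HL.shape,
                  self.H_HH.shape}
        if len(shapes) != 1:
            raise DimensionError(f"sub-band shapes differ: {shapes}")
        if self.level < 1:
            raise ConfigurationError("level must be >= 1")

    @property
    def bands(self) -> tuple[np.ndarray, ...]:
        return (self.L, self.H_LH, self.H_HL, self.H_HH)

    def energy(self) -> float:
        return float(sum(np.sum(np.square(b, dtype=np.float64))
                         for b in self.bands))


def _analysis_1d(x: np.ndarray, filt: np.ndarray, axis: int) -> np.ndarray:
    """Periodized stride-2 correlation along ``axis`` (length must be even)."""
    x = np.moveaxis(x, axis, -1)
    n = x.shape[-1]
    taps = len(filt)
    if taps > 2:
        x = np.concatenate([x, x[..., :taps - 2]], axis=-1)
    windows = np.lib.stride_tricks.sliding_window_view(x, taps, axis=-1)
    out = windows[..., ::2, :] @ filt
    return np.moveaxis(out[..., : n // 2, ], -1, axis)


def _synthesis_1d(lo: np.ndarray, hi: np.ndarray, low_f: np.ndarray,
                  high_f: np.ndarray, axis: int) -> np.ndarray:
    """Inverse of :func:`_analysis_1d` for an orthonormal filter pair."""
    lo = np.moveaxis(lo, axis, -1)
    hi = np.moveaxis(hi, axis, -1)
    n = 2 * lo.shape[-1]
    taps = len(low_f)
    out = np.zeros(lo.shape[:-1] + (n,), dtype=np.float64)
    for k in range(taps):
        idx = (np.arange(lo.shape[-1]) * 2 + k) % n
        np.add.at(out, (..., idx), lo * low_f[k] + hi * high_f[k])
    return np.moveaxis(out, -1, axis)


def _pad_even(x: np.ndarray) -> tuple[np.ndarray, tuple[int, int]]:
    h, w = x.shape[-2:]
    ph, pw = h % 2, w % 2
    if ph or pw:
        width = [(0, 0)] * (x.ndim - 2) + [(0, ph), (0, pw)]
        x = np.pad(x, width, mode="reflect")
    return x, (h, w)


def dwt2d(x: np.ndarray, family: str = "haar",
          levels: int = 1) -> list[WaveletSubbands]:
    """Decompose a feature map into per-level sub-band pyramids.

    Parameters
    ----------
    x : ndarray, ``(..., H, W)`` with ``H, W >= 2``.
    family : registered orthonormal wavelet family name.
    levels : decomposition depth; level ``l+1`` decomposes level ``l``'s
        low-frequency band.

    Returns
    -------
    list of :class:`WaveletSubbands`, shallowest level first.
    """
    if family not in WAVELET_FAMILIES:
        raise ConfigurationError(
            f"unknown wavelet family {family!r}; "
            f"known: {sorted(WAVELET_FAMILIES)}")
    if levels < 1:
        raise ConfigurationError("levels must be >= 1")
    x = np.asarray(x, dtype=np.float64)
    if x.ndim < 2 or x.shape[-1] < 2 or x.shape[-2] < 2:
        raise DimensionError(f"need at least 2x2 spatial input, got {x.shape}")
    low_f, high_f = WAVELET_FAMILIES[family]
    out: list[WaveletSubbands] = []
    cur = x
    for lvl in range(1, levels + 1):
        if cur.shape[-1] < 2 or cur.shape[-2] < 2:
            raise DimensionError(
                f"input too small for {levels} levels at level {lvl}")
        cur, orig = _pad_even(cur)
        lo_w = _analysis_1d(cur, low_f, axis=-1)     # width pass first
        hi_w = _analysis_1d(cur, high_f, axis=-1)
        sb = WaveletSubbands(
            L=_analysis_1d(lo_w, low_f, axis=-2),
            H_LH=_analysis_1d(hi_w, low_f, axis=-2),
            H_HL=_analysis_1d(lo_w, high_f, axis=-2),
            H_HH=_analysis_1d(hi_w, high_f, axis=-2),
            level=lvl, orig_shape=orig)
        out.append(sb)
        cur = sb.L
    return out


def iwt2d(sb: WaveletSubbands | list[WaveletSubbands],
          family: str = "haar") -> np.ndarray:
    """Reconstruct the original map from :func:`dwt2d` output.

    Exact left-inverse for orthonormal families (up to float tolerance).
    """
    if family not in WAVELET_FAMILIES:
        raise ConfigurationError(f"unknown wavelet family {family!r}")
    low_f, high_f = WAVELET_FAMILIES[family]
    pyramid = [sb] if isinstance(sb, WaveletSubbands) else list(sb)
    if not pyramid:
        raise DimensionError("empty sub-band pyramid")
    cur = None
    for level in reversed(pyramid):
        L = level.L if cur is None else cur
        if L.shape != level.H_LH.shape:
            raise DimensionError(
                f"low band {L.shape} inconsistent with high bands "
                f"{level.H_LH.shape}")
        lo_w = _synthesis_1d(L, level.H_HL, low_f, high_f, axis=-2)
        hi_w = _synthesis_1d(level.H_LH, level.H_HH, low_f, high_f, axis=-2)
        cur = _synthesis_1d(lo_w, hi_w, low_f, high_f, axis=-1)
        if level.orig_shape is not None:
            h, w = level.orig_shape
            cur = cur[..., :h, :w]
    return cur


# --------------------------------------------------------------------------
# WTConv layer


@dataclass
class WTConvSpec:
    """Configuration of a wavelet-domain convolution layer."""

    in_channels: int
    out_channels: int
    kernel_size: int = 3
    levels: int = 1
    wavelet_family: str = "haar"
    residual: bool = True

    def __post_init__(self):
        if self.levels < 1:
            raise ConfigurationError("levels must be >= 1")
        if self.kernel_size % 2 != 1:
            raise ConfigurationError("kernel_size must be odd")
        if self.in_channels != self.out_channels:
            raise ConfigurationError(
                "wavelet-domain processing is depthwise; in_channels must "
                "equal out_channels")
        if self.wavelet_family != "haar":
            raise ConfigurationError(
                "the differentiable WTConv layer supports the Haar family "
                "only; use dwt2d/iwt2d for other families")


def _haar_dwt_t(x: nn.Tensor) -> tuple[nn.Tensor, nn.Tensor, nn.Tensor, nn.Tensor]:
    a = x[..., 0::2, 0::2]
    b = x[..., 0::2, 1::2]
    c = x[..., 1::2, 0::2]
    d = x[..., 1::2, 1::2]
    L = (a + b + c + d) * 0.5
    lh = (a - b + c - d) * 0.5
    hl = (a + b - c - d) * 0.5
    hh = (a - b - c + d) * 0.5
    return L, lh, hl, hh


def _haar_iwt_t(L: nn.Tensor, lh: nn.Tensor, hl: nn.Tensor,
                hh: nn.Tensor) -> nn.Tensor:
    a = (L + lh + hl + hh) * 0.5
    b = (L - lh + hl - hh) * 0.5
    c = (L + lh - hl - hh) * 0.5
    d = (L - lh - hl + hh) * 0.5
    n, ch, h, w = L.shape
    row0 = nn.stack([a, b], axis=-1).reshape(n, ch, h, 2 * w)
    row1 = nn.stack([c, d], axis=-1).reshape(n, ch, h, 2 * w)
    return nn.stack([row0, row1], axis=3).reshape(n, ch, 2 * h, 2 * w)


class WTConv(nn.Module):
    """Wavelet-transform convolution.

    Decomposes the input, applies an independent depthwise convolution to
    each sub-band (the learnable sub-band operator), reconstructs with the
    inverse transform, and adds a pointwise residual path.  Output spatial
    size equals input spatial size; spatial dims must be divisible by
    ``2**levels``.
    """

    def __init__(self, spec: WTConvSpec):
        super().__init__()
        self.spec = spec
        c, k = spec.in_channels, spec.kernel_size
        # every level operates on its three high-frequency bands; only the
        # deepest level also transforms the remaining low band
        self.subband_ops = nn.ModuleList()
        for lvl in range(spec.levels):
            n_ops = 4 if lvl == spec.levels - 1 else 3
            level_ops = nn.ModuleList(
                nn.Conv2d(c, c, k, 1, k // 2, groups=c, bias=True)
                for _ in range(n_ops))
            self.subband_ops.append(level_ops)
        self.pointwise = nn.Conv2d(c, c, 1, bias=True) if spec.residual \
            else None

    def identity_init(self):
        """Set every sub-band operator to a unit centre tap (transform ->
        identity -> inverse), for degradation testing."""
        k = self.spec.kernel_size
        for level_ops in self.subband_ops:
            for op in level_ops:
                op.weight.data[:] = 0.0
                op.weight.data[:, 0, k // 2, k // 2] = 1.0
                op.bias.data[:] = 0.0
        if self.pointwise is not None:
            self.pointwise.weight.data[:] = 0.0
            self.pointwise.bias.data[:] = 0.0
        return self

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        if x.shape[1] != self.spec.in_channels:
            raise DimensionError(
                f"expected {self.spec.in_channels} channels, got {x.shape[1]}")
        h, w = x.shape[-2:]
        if h % (2 ** self.spec.levels) or w % (2 ** self.spec.levels):
            raise DimensionError(
                f"spatial size {h}x{w} not divisible by 2^{self.spec.levels}")
        # recursive decomposition of the low band
        stack: list[tuple] = []
        cur = x
        for level_ops in self.subband_ops:
            L, lh, hl, hh = _haar_dwt_t(cur)
            stack.append((level_ops, lh, hl, hh))
            cur = L
        # deepest low band is processed by that level's extra operator
        cur = self.subband_ops[-1][3](cur)
        for level_ops, lh, hl, hh in reversed(stack):
            cur = _haar_iwt_t(cur, level_ops[0](lh), level_ops[1](hl),
                              level_ops[2](hh))
        if self.pointwise is not None:
            cur = cur + self.pointwise(x)
        return cur


def wtconv_forward(x: np.ndarray, layer: WTConv) -> np.ndarray:
    """Run a :class:`WTConv` layer on a ``C x H x W`` numpy map."""
    x = np.asarray(x, dtype=np.float32)
    if x.ndim != 3:
        raise DimensionError("expected a C x H x W map")
    with nn.no_grad():
        out = layer(nn.Tensor(x[None]))
    return out.data[0]
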