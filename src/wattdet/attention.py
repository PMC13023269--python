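"""Channel/spatial attention with Sobel edge cues and cross-scale sharing.

The block runs channel attention first (global average + max descriptors
through a shared two-layer MLP), then spatial attention (channel-wise mean
map, max map and a Sobel edge-magnitude map concatenated and convolved to
a single sigmoid gate).  The cross-scale extension averages each stage's
spatial gate with the nearest-neighbour-resampled gates of adjacent
stages before applying it.

Functional entry points (``channel_attention``, ``sobel_edges``,
``spatial_attention``, ``scsa_block``) operate on plain ``C x H x W``
numpy arrays; the :class:`ScsaGate` module is the differentiable form
used inside the detector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import nn
from .errors import ConfigurationError, DimensionError

__all__ = [
    "SOBEL_X", "SOBEL_Y", "ScsaConfig",
    "ChannelAttention", "SpatialAttention", "ScsaGate",
    "channel_attention", "sobel_edges", "spatial_attention", "scsa_block",
]

#: Standard 3x3 Sobel kernels; ``SOBEL_X`` responds to horizontal gradients
#: (vertical edges), ``SOBEL_Y`` to vertical gradients.
SOBEL_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=np.float32)
SOBEL_Y = SOBEL_X.T.copy()

STAGE_ORDER = ("P2", "P3", "P4", "P5")


@dataclass
class ScsaConfig:
    """Configuration of the cross-scale attention block."""

    reduction: int = 16
    stages: tuple[str, ...] = ("P3", "P4", "P5")
    cross_scale: bool = True

    def __post_init__(self):
        if self.reduction < 1:
            raise ConfigurationError("reduction must be >= 1")
        bad = [s for s in self.stages if s not in STAGE_ORDER]
        if bad:
            raise ConfigurationError(f"unknown stage tags {bad}")


class ChannelAttention(nn.Module):
    """Per-channel sigmoid gate from pooled descriptors and a shared MLP."""

    def __init__(self, channels: int, reduction: int = 16):
        super().__init__()
        self.channels = channels
        hidden = max(1, channels // reduction)
        self.fc1 = nn.Linear(channels, hidden, bias=True)
        self.fc2 = nn.Linear(hidden, channels, bias=True)

    def gate(self, x: nn.Tensor) -> nn.Tensor:
        z_avg = x.mean(axis=(2, 3))                 # N,C
        z_max = x.max(axis=(2, 3))
        logits = self.fc2(self.fc1(z_avg).relu()) \
            + self.fc2(self.fc1(z_max).relu())
        n, c = logits.shape
        return logits.sigmoid().reshape(n, c, 1, 1)

    def forward(self, x: nn.Tensor) -> tuple[nn.Tensor, nn.Tensor]:
        mc = self.gate(x)
        return mc, mc * x


def _sobel_pair(xt: nn.Tensor) -> nn.Tensor:
    """Edge magnitude of a (N,1,H,W) tensor with reflect boundary."""
    wx = nn.Tensor(SOBEL_X.reshape(1, 1, 3, 3))
    wy = nn.Tensor(SOBEL_Y.reshape(1, 1, 3, 3))
    xp = xt.pad2d(1, mode="reflect")
    gx = nn.conv2d(xp, wx)
    gy = nn.conv2d(xp, wy)
    return (gx * gx + gy * gy + 1e-12) ** 0.5


class SpatialAttention(nn.Module):
    """Spatial sigmoid gate from [mean, max, edge] maps and a k x k conv."""

    def __init__(self, kernel_size: int = 7):
        super().__init__()
        if kernel_size % 2 != 1:
            raise ConfigurationError("spatial kernel must be odd")
        self.conv = nn.Conv2d(3, 1, kernel_size, 1, kernel_size // 2,
                              bias=True)

    def gate(self, x: nn.Tensor) -> nn.Tensor:
        mean_map = x.mean(axis=1, keepdims=True)
        max_map = x.max(axis=1, keepdims=True)
        edge_map = _sobel_pair(mean_map)
        stacked = nn.cat([mean_map, max_map, edge_map], axis=1)
        return self.conv(stacked).sigmoid()

    def forward(self, x: nn.Tensor) -> tuple[nn.Tensor, nn.Tensor]:
        ms = self.gate(x)
        return ms, ms * x


class ScsaGate(nn.Module):
    """Channel-then-spatial gate with optional causal cross-scale sharing.

    Inside the detector the backbone runs shallow to deep, so a stage can
    only share with the *previous* stage's already-computed gate; the gate
    therefore averages its own spatial map with the stride-2 downsampled
    map cached by the preceding tagged stage.  The symmetric two-sided
    rule is available through :func:`scsa_block`.
    """

    def __init__(self, channels: int, reduction: int = 16, stage: str = "",
                 kernel_size: int = 7):
        super().__init__()
        self.stage = stage
        self.ca = ChannelAttention(channels, reduction)
        self.sa = SpatialAttention(kernel_size)
        self.context: dict | None = None   # set by the host detector

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        _, xc = self.ca(x)
        ms = self.sa.gate(xc)
        if self.context is not None and self.stage:
            idx = STAGE_ORDER.index(self.stage)
            prev = STAGE_ORDER[idx - 1] if idx > 0 else None
            shared = self.context.get(prev)
            self.context[self.stage] = ms
            if shared is not None:
                factor = shared.shape[-1] // ms.shape[-1]
                if factor > 1:
                    shared = shared[..., ::factor, ::factor]
                ms = (ms + shared) * 0.5
        return ms * xc


# --------------------------------------------------------------------------
# Functional API on C x H x W numpy maps


def channel_attention(x: np.ndarray, params: ChannelAttention
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Return ``(M_c, M_c * x)`` for a ``C x H x W`` map."""
    x = np.asarray(x, dtype=np.float32)
    if x.ndim != 3:
        raise DimensionError("expected C x H x W input")
    with nn.no_grad():
        mc, out = params(nn.Tensor(x[None]))
    return mc.data[0], out.data[0]


def sobel_edges(xt: np.ndarray) -> np.ndarray:
    """Edge magnitude ``sqrt((Sx*x)^2 + (Sy*x)^2)`` of a 2-D map."""
    xt = np.asarray(xt, dtype=np.float64)
    if xt.ndim != 2:
        raise DimensionError("expected a single-channel H x W map")
    if xt.shape[0] < 3 or xt.shape[1] < 3:
        raise DimensionError("need at least 3x3 input")
    gx = ndimage.correlate(xt, SOBEL_X.astype(np.float64), mode="mirror")
    gy = ndimage.correlate(xt, SOBEL_Y.astype(np.float64), mode="mirror")
    return np.sqrt(gx * gx + gy * gy)


def spatial_attention(xp: np.ndarray, params: SpatialAttention
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Return ``(M_s, M_s * xp)`` for a channel-attended ``C x H x W`` map."""
    xp = np.asarray(xp, dtype=np.float32)
    if xp.ndim != 3:
        raise DimensionError("expected C x H x W input")
    with nn.no_grad():
        ms, out = params(nn.Tensor(xp[None]))
    return ms.data[0], out.data[0]


def _resample_to(m: np.ndarray, hw: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbour resampling between power-of-two related sizes."""
    h, w = m.shape[-2:]
    th, tw = hw
    if (h, w) == (th, tw):
        return m
    if th > h:
        f = th // h
        return np.repeat(np.repeat(m, f, axis=-2), f, axis=-1)
    f = h // th
    return m[..., ::f, ::f]


@dataclass
class ScsaBlockParams:
    """Per-stage attention parameters used by :func:`scsa_block`."""

    gates: dict[str, tuple[ChannelAttention, SpatialAttention]] = \
        field(default_factory=dict)

    @classmethod
    def build(cls, channels_by_stage: dict[str, int],
              cfg: ScsaConfig) -> "ScsaBlockParams":
        gates = {s: (ChannelAttention(c, cfg.reduction), SpatialAttention())
                 for s, c in channels_by_stage.items()}
        return cls(gates)


def scsa_block(features_by_stage: dict[str, np.ndarray], cfg: ScsaConfig,
               params: ScsaBlockParams | None = None
               ) -> dict[str, np.ndarray]:
    """Apply channel-then-spatial attention per stage with map sharing.

    When ``cfg.cross_scale`` is on, each stage's spatial map is averaged
    with the nearest-neighbour-resampled maps of its adjacent stages
    before application.  Stages must be spatially nested by factors of 2.
    """
    stages = [s for s in STAGE_ORDER if s in features_by_stage]
    if set(features_by_stage) - set(stages):
        raise ConfigurationError(
            f"unknown stage tags {set(features_by_stage) - set(stages)}")
    for a, b in zip(stages[:-1], stages[1:]):
        ha = features_by_stage[a].shape[-1]
        hb = features_by_stage[b].shape[-1]
        gap = STAGE_ORDER.index(b) - STAGE_ORDER.index(a)
        if ha != hb * (2 ** gap):
            raise ConfigurationError(
                f"stages {a}({ha}) and {b}({hb}) are not nested by "
                f"factor {2 ** gap}")
    if params is None:
        params = ScsaBlockParams.build(
            {s: features_by_stage[s].shape[0] for s in stages}, cfg)

    attended: dict[str, np.ndarray] = {}
    own_maps: dict[str, np.ndarray] = {}
    for s in stages:
        ca, sa = params.gates[s]
        _, xc = channel_attention(features_by_stage[s], ca)
        ms, _ = spatial_attention(xc, sa)
        attended[s] = xc
        own_maps[s] = ms

    out: dict[str, np.ndarray] = {}
    for i, s in enumerate(stages):
        ms = own_maps[s]
        if cfg.cross_scale:
            neigh = [own_maps[t] for t in
                     ([stages[i - 1]] if i > 0 else [])
                     + ([stages[i + 1]] if i + 1 < len(stages) else [])]
            if neigh:
                maps = [ms] + [_resample_to(m, ms.shape[-2:]) for m in neigh]
                ms = np.mean(maps, axis=0)
        out[s] = ms * attended[s]
    return out
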