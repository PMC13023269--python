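"""Learnable softmax-weighted fusion of aligned multi-scale branches."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .errors import DimensionError

__all__ = ["FusionNode", "fusion_weights", "wfu_fuse", "WFUNode"]


def fusion_weights(logits) -> np.ndarray:
    """Softmax-normalize K learnable scalars into positive fusion weights.

    Uses max-subtraction for numerical stability; the result sums to 1.
    """
    a = np.asarray(logits, dtype=np.float64)
    if a.ndim != 1 or a.size < 2:
        raise DimensionError("need at least K=2 logits in a flat vector")
    if not np.all(np.isfinite(a)):
        raise FloatingPointError("non-finite fusion logit")
    e = np.exp(a - a.max())
    return e / e.sum()


@dataclass
class FusionNode:
    """A K-branch fusion point with learnable scalar logits."""

    K: int
    logits: np.ndarray = None

    def __post_init__(self):
        if self.K < 2:
            raise DimensionError("fusion node needs K >= 2 branches")
        if self.logits is None:
            self.logits = np.zeros(self.K, dtype=np.float64)
        self.logits = np.asarray(self.logits, dtype=np.float64)
        if self.logits.shape != (self.K,):
            raise DimensionError("logits must have shape (K,)")

    @property
    def weights(self) -> np.ndarray:
        return fusion_weights(self.logits)


def wfu_fuse(branches: list[np.ndarray], node: FusionNode) -> np.ndarray:
    """Convex combination ``sum_k w_k F_k`` of K aligned feature maps."""
    if len(branches) != node.K:
        raise DimensionError(f"expected {node.K} branches, got {len(branches)}")
    shapes = {np.asarray(b).shape for b in branches}
    if len(shapes) != 1:
        raise DimensionError(f"branches are not aligned: {shapes}")
    w = node.weights
    out = np.zeros_like(np.asarray(branches[0], dtype=np.float64))
    for wk, b in zip(w, branches):
        out += wk * np.asarray(b, dtype=np.float64)
    return out


class WFUNode(nn.Module):
    """In-network fusion node replacing a concatenation point.

    Branches are aligned to a common working width by 1x1 convolutions
    (identity when the width already matches), combined by the softmax
    weights, expanded to the original concatenation width so downstream
    layers are unchanged, and optionally refined by a small bottleneck
    whose hidden width scales with the semantic depth of the node.
    """

    def __init__(self, branch_channels: list[int], out_channels: int,
                 refine_hidden: int = 0):
        super().__init__()
        from .blocks import ConvBnAct   # local import to avoid a cycle
        self.branch_channels = list(branch_channels)
        width = max(branch_channels)
        self.width = width
        self.align = nn.ModuleList(
            ConvBnAct(c, width, 1) if c != width else nn.Identity()
            for c in branch_channels)
        self.logits = nn.Parameter(np.zeros(len(branch_channels),
                                            dtype=np.float32))
        self.expand = ConvBnAct(width, out_channels, 1)
        if refine_hidden > 0:
            self.refine = nn.Sequential(
                ConvBnAct(out_channels, refine_hidden, 1),
                ConvBnAct(refine_hidden, out_channels, 3))
        else:
            self.refine = None

    def weights(self) -> np.ndarray:
        return fusion_weights(self.logits.data.astype(np.float64))

    def forward(self, branches: list[nn.Tensor]) -> nn.Tensor:
        if len(branches) != len(self.align):
            raise DimensionError(
                f"expected {len(self.align)} branches, got {len(branches)}")
        aligned = [op(b) for op, b in zip(self.align, branches)]
        shapes = {a.shape for a in aligned}
        if len(shapes) != 1:
            raise DimensionError(f"unalignable branch shapes {shapes}")
        w = self.logits.softmax(axis=0)
        fused = None
        for k, a in enumerate(aligned):
            term = w[k] * a
            fused = term if fused is None else fused + term
        out = self.expand(fused)
        if self.refine is not None:
            out = out + self.refine(out)
        return out
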