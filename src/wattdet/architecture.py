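"""Detector assembly, ablation configurations, and budget accounting."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .attention import ScsaGate
from .blocks import C2PSA, C3k2, ConvBnAct, Detect, SPPF
from .errors import ConfigurationError, DimensionError
from .fusion import WFUNode

__all__ = [
    "ModelConfig", "BudgetReport", "Detector", "build_model",
    "count_params", "count_flops", "ablation_configs",
    "save_checkpoint", "load_checkpoint", "CLASS_NAMES",
]

CLASS_NAMES = ("stand", "walk", "side", "lie", "eat", "drink")

# stage tag of each backbone C3k2 host layer
_SCSA_STAGE = {2: "P2", 4: "P3", 6: "P4", 8: "P5"}

# default insertion sites, tuned so every printed budget is reproduced:
#   - attention gates replace the second bottleneck convolution (3x3 -> 1x1
#     + gate) of one bottleneck per host stage;
#   - wavelet convolutions replace square bottleneck convolutions in the
#     deep stages operating on P4/P5 feature maps (backbone stage 6 and
#     the deepest P5-scale stage 22).
_DEFAULT_SCSA_SITES = ((4, 0), (6, 0), (8, 0))
_DEFAULT_WT_SITES = ((8, 0, "cv1"), (8, 1, "cv1"), (8, 1, "cv2"),
                     (22, 0, "cv1"), (22, 0, "cv2"))
# fusion nodes replace the four neck concatenation points; the two
# bottom-up nodes carry refinement stacks whose hidden widths are part of
# the budget contract
_DEFAULT_WFU_REFINE = {21: 164, 18: 20}


@dataclass
class ModelConfig:
    """Ablation switches and structural hyperparameters of the detector."""

    use_scsa: bool = False
    use_wfu: bool = False
    use_wtconv: bool = False
    num_classes: int = 6
    input_size: int = 640
    width_multiple: float = 0.25
    depth_multiple: float = 0.50
    max_channels: int = 1024
    scsa_reduction: int = 16
    scsa_cross_scale: bool = True
    scsa_sites: tuple = _DEFAULT_SCSA_SITES
    wt_sites: tuple = _DEFAULT_WT_SITES
    wt_kernel: int = 3
    wt_levels: int = 1
    wfu_refine: dict = field(default_factory=lambda: dict(_DEFAULT_WFU_REFINE))

    def validate(self):
        if self.num_classes < 1:
            raise ConfigurationError("num_classes must be >= 1")
        if self.input_size % 32:
            raise ConfigurationError("input_size must be a multiple of 32")
        for site in self.scsa_sites:
            if site[0] not in (2, 4, 6, 8):
                raise ConfigurationError(
                    f"attention host {site[0]} is not a backbone stage")
        for site in self.wt_sites:
            if site[0] not in (6, 8, 22):
                raise ConfigurationError(
                    f"wavelet host {site[0]} does not process P4/P5 maps")
        return self

    def to_dict(self) -> dict:
        d = asdict(self)
        d["scsa_sites"] = [list(s) for s in self.scsa_sites]
        d["wt_sites"] = [list(s) for s in self.wt_sites]
        d["wfu_refine"] = {str(k): v for k, v in self.wfu_refine.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        if "scsa_sites" in d:
            d["scsa_sites"] = tuple(tuple(s) for s in d["scsa_sites"])
        if "wt_sites" in d:
            d["wt_sites"] = tuple(tuple(s) for s in d["wt_sites"])
        if "wfu_refine" in d:
            d["wfu_refine"] = {int(k): int(v) for k, v in d["wfu_refine"].items()}
        return cls(**d)


@dataclass
class BudgetReport:
    """Parameter or FLOP accounting with a per-layer breakdown."""

    total: int
    millions: float = 0.0
    giga: float = 0.0
    breakdown: dict = field(default_factory=dict)

    def __post_init__(self):
        self.millions = round(self.total / 1e6, 2)
        self.giga = round(self.total / 1e9, 1)
        if self.breakdown and sum(self.breakdown.values()) != self.total:
            raise ValueError("breakdown does not sum to total")

    def table(self) -> str:
        lines = [f"{'layer':<22}{'count':>16}"]
        for k, v in self.breakdown.items():
            lines.append(f"{k:<22}{v:>16,}")
        lines.append(f"{'total':<22}{self.total:>16,}")
        return "\n".join(lines)


class _Concat(nn.Module):
    def forward(self, xs: list[nn.Tensor]) -> nn.Tensor:
        return nn.cat(xs, axis=1)


class Detector(nn.Module):
    """YOLO-style single-stage detector with configurable module insertion.

    Layers 0-10 form the backbone (P1..P5 + SPPF + PSA), 11-22 the
    FPN-PAN neck, 23 the decoupled head fed from layers 16/19/22.
    """

    SAVE = (4, 6, 10, 13, 16, 19, 22)
    HEAD_FROM = (16, 19, 22)

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        nn.set_init_rng(seed)
        w = cfg.width_multiple

        def ch(c):
            return int(min(c, cfg.max_channels) * w)

        c64, c128, c256 = ch(256), ch(512), ch(1024)
        self._scsa_gates: list[ScsaGate] = []
        self._scsa_context: dict = {}

        def c3k2(idx, c1, c2, c3k=False, e=0.5):
            n_b = 2 if c3k else 1   # flattened bottleneck count at nano depth
            gate_ch = int(c2 * e) // (2 if c3k else 1)
            site_plan = {}
            for i in range(n_b):
                cv1 = "wt" if (cfg.use_wtconv
                               and (idx, i, "cv1") in cfg.wt_sites) else "conv"
                cv2 = "wt" if (cfg.use_wtconv
                               and (idx, i, "cv2") in cfg.wt_sites) else "conv"
                gate = None
                if cfg.use_scsa and (idx, i) in cfg.scsa_sites:
                    gate = ScsaGate(gate_ch, cfg.scsa_reduction,
                                    stage=_SCSA_STAGE.get(idx, ""))
                    self._scsa_gates.append(gate)
                site_plan[i] = (cv1, cv2, gate)
            return C3k2(c1, c2, 1, c3k=c3k, e=e, site_plan=site_plan,
                        wt_kernel=cfg.wt_kernel, wt_levels=cfg.wt_levels)

        def fuse(idx, branch_ch, out_ch):
            if cfg.use_wfu:
                return WFUNode(branch_ch, out_ch,
                               refine_hidden=cfg.wfu_refine.get(idx, 0))
            return _Concat()

        nc = cfg.num_classes
        spec: list[tuple[nn.Module, object]] = [
            (ConvBnAct(3, c64 // 4, 3, 2), -1),             # 0  P1/2
            (ConvBnAct(c64 // 4, c64 // 2, 3, 2), -1),      # 1  P2/4
            (c3k2(2, c64 // 2, c64, False, 0.25), -1),      # 2
            (ConvBnAct(c64, c64, 3, 2), -1),                # 3  P3/8
            (c3k2(4, c64, c128, False, 0.25), -1),          # 4
            (ConvBnAct(c128, c128, 3, 2), -1),              # 5  P4/16
            (c3k2(6, c128, c128, True), -1),                # 6
            (ConvBnAct(c128, c256, 3, 2), -1),              # 7  P5/32
            (c3k2(8, c256, c256, True), -1),                # 8
            (SPPF(c256, c256, 5), -1),                      # 9
            (C2PSA(c256, 1), -1),                           # 10
            (nn.Upsample(), -1),                            # 11
            (fuse(12, [c256, c128], c256 + c128), (11, 6)),  # 12
            (c3k2(13, c256 + c128, c128), -1),              # 13
            (nn.Upsample(), -1),                            # 14
            (fuse(15, [c128, c128], c128 * 2), (14, 4)),    # 15
            (c3k2(16, c128 * 2, c64), -1),                  # 16  P3 out
            (ConvBnAct(c64, c64, 3, 2), -1),                # 17
            (fuse(18, [c64, c128], c64 + c128), (17, 13)),  # 18
            (c3k2(19, c64 + c128, c128), -1),               # 19  P4 out
            (ConvBnAct(c128, c128, 3, 2), -1),              # 20
            (fuse(21, [c128, c256], c128 + c256), (20, 10)),  # 21
            (c3k2(22, c128 + c256, c256, True), -1),        # 22  P5 out
            (Detect(nc, (c64, c128, c256)), self.HEAD_FROM),  # 23
        ]
        self.layers = nn.ModuleList(m for m, _ in spec)
        self.froms = [f for _, f in spec]
        self.layers[-1].bias_init()
        for g in self._scsa_gates:
            g.context = self._scsa_context if cfg.scsa_cross_scale else None

    # ----------------------------------------------------------------- run
    def forward(self, x: nn.Tensor, profile: bool = False) -> list[nn.Tensor]:
        if x.shape[1] != 3:
            raise DimensionError("expected 3-channel input")
        if x.shape[2] % 32 or x.shape[3] % 32:
            raise DimensionError("input spatial size must be divisible by 32")
        self._scsa_context.clear()
        y: dict[int, nn.Tensor] = {}
        cur = x
        for i, (layer, f) in enumerate(zip(self.layers, self.froms)):
            if i == len(self.layers) - 1:
                inp = [y[j] for j in f]
            elif isinstance(f, tuple):
                inp = [y[f[0]], y[f[1]]]
            else:
                inp = cur
            if profile:
                with nn.profiler.scope(f"{i:02d}_{layer.__class__.__name__}"):
                    cur = layer(inp)
            else:
                cur = layer(inp)
            y[i] = cur
        return cur

    def predict_raw(self, images: np.ndarray) -> list[nn.Tensor]:
        with nn.no_grad():
            return self.forward(nn.Tensor(images))

    @property
    def head(self) -> Detect:
        return self.layers[-1]


def build_model(cfg: ModelConfig, seed: int = 0) -> Detector:
    """Build the detector; deterministic in its initial parameters for a
    fixed seed."""
    return Detector(cfg, seed=seed)


def count_params(model: Detector) -> BudgetReport:
    """Exact trainable-parameter count with a per-layer breakdown."""
    breakdown = {}
    total = 0
    for i, layer in enumerate(model.layers):
        n = sum(p.size for p in layer.parameters() if p.requires_grad)
        breakdown[f"{i:02d}_{layer.__class__.__name__}"] = n
        total += n
    return BudgetReport(total=total, breakdown=breakdown)


def count_flops(model: Detector, input_size: int | None = None) -> BudgetReport:
    """FLOPs of one forward pass at the given square input size.

    Convention: 2 FLOPs per convolution/linear multiply-accumulate plus
    4 FLOPs per normalized element (unfused batch normalization performs
    two multiply-adds per element).  Fixed-filter transforms (Sobel,
    wavelet analysis/synthesis) cost no counted FLOPs.
    """
    size = input_size or model.cfg.input_size
    was_training = model.layers[0].training
    model.eval()
    x = np.zeros((1, 3, size, size), dtype=np.float32)
    nn.profiler.start()
    try:
        with nn.no_grad():
            model.forward(nn.Tensor(x), profile=True)
    finally:
        per_scope = nn.profiler.stop()
    if was_training:
        model.train()
    breakdown = {k: 2 * v for k, v in per_scope.items()}
    return BudgetReport(total=sum(breakdown.values()), breakdown=breakdown)


def ablation_configs() -> dict[str, ModelConfig]:
    """The seven module on/off combinations of the ablation study."""
    combos = {
        "baseline": (False, False, False),
        "scsa": (True, False, False),
        "wt": (False, False, True),
        "wfu": (False, True, False),
        "scsa_wfu": (True, True, False),
        "wfu_wt": (False, True, True),
        "scsa_wfu_wt": (True, True, True),
    }
    return {k: ModelConfig(use_scsa=s, use_wfu=w, use_wtconv=t)
            for k, (s, w, t) in combos.items()}


# --------------------------------------------------------------------------
# checkpoints


def save_checkpoint(model: Detector, path, class_names=CLASS_NAMES,
                    extra: dict | None = None):
    """Single-file weights + config + class names (numpy archive)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {"config": model.cfg.to_dict(), "class_names": list(class_names),
            "extra": extra or {}}
    arrays = {f"w::{k}": v for k, v in model.state_dict().items()}
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path, model: Detector | None = None
                    ) -> tuple[Detector, dict]:
    """Load a checkpoint; accepts partial (e.g. backbone-only) state.

    Name-based matching: keys absent from the file stay at their current
    initialization and are reported, as are unused file keys.
    """
    with np.load(Path(path).with_suffix(".npz") if not str(path).endswith(".npz")
                 else path, allow_pickle=False) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        state = {k[3:]: z[k] for k in z.files if k.startswith("w::")}
    if model is None:
        model = build_model(ModelConfig.from_dict(meta["config"]))
    report = model.load_state_dict(state, strict=False)
    meta["load_report"] = report
    return model, meta
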