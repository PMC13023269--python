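"""Seeded generator of farm-like test scenes with exact box labels.

Each "pig" is an elliptical blob whose class is encoded purely by pose
geometry and context patches (upright ellipse = stand, tilted with leg
stubs = walk, long flat = side, compact flat = lie, dark trough patch at
the head = eat, blue nipple patch = drink).  The encoding is synthetic
and *not* biologically meaningful; it only provides separable classes
for overfit and metrics tests without any dataset download.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .architecture import CLASS_NAMES
from .dataio import (BoxAnnotation, DatasetItem, write_dataset_yaml,
                     write_yolo_labels)
from .errors import ConfigurationError, GenerationError

__all__ = ["SceneSpec", "generate_scene", "generate_dataset",
           "random_specs", "items_from_specs"]

BRIGHTNESS_REGIMES = {"normal": 1.0, "backlit": 1.35, "low": 0.55}

#: per-class body geometry: (aspect w/h, tilt degrees, context patch)
_GEOMETRY = {
    "stand": (0.60, 0.0, None),
    "walk": (0.75, 25.0, "legs"),
    "side": (2.60, 0.0, None),
    "lie": (1.15, 0.0, None),
    "eat": (1.40, 0.0, "trough"),
    "drink": (1.40, 0.0, "nipple"),
}

_BODY_COLOR = {
    "stand": (228, 170, 160),
    "walk": (225, 185, 150),
    "side": (210, 160, 170),
    "lie": (235, 180, 175),
    "eat": (220, 175, 145),
    "drink": (215, 165, 185),
}


@dataclass
class SceneSpec:
    """Parameters of one synthetic scene."""

    image_size: int = 128
    counts: dict = field(default_factory=dict)   # class name -> instances
    occlusion: float = 0.15
    brightness_regime: str = "normal"
    clutter: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.occlusion < 1.0:
            raise ConfigurationError("occlusion must lie in [0, 1)")
        if self.brightness_regime not in BRIGHTNESS_REGIMES:
            raise ConfigurationError(
                f"unknown brightness regime {self.brightness_regime!r}")
        for name, n in self.counts.items():
            if name not in CLASS_NAMES:
                raise ConfigurationError(f"unknown class {name!r}")
            if n < 0:
                raise ConfigurationError("counts must be >= 0")


def _background(rng: np.random.Generator, size: int,
                clutter: float) -> np.ndarray:
    base = rng.uniform(70, 110)
    img = np.full((size, size, 3), base, dtype=np.float64)
    noise = rng.normal(0, 6, (size, size, 1))
    img += noise
    # low-frequency mottling
    coarse = rng.normal(0, 12, (size // 8 + 1, size // 8 + 1))
    img += np.kron(coarse, np.ones((8, 8)))[:size, :size, None]
    n_clutter = int(clutter * 12)
    for _ in range(n_clutter):
        x0, y0 = rng.integers(0, size, 2)
        w = int(rng.integers(size // 16, size // 4))
        h = int(rng.integers(2, size // 16))
        if rng.random() < 0.5:
            w, h = h, w
        shade = rng.uniform(-35, 35)
        img[y0:y0 + h, x0:x0 + w] += shade
    return img


def _ellipse_mask(size: int, cx, cy, rx, ry, tilt_deg) -> np.ndarray:
    ys, xs = np.mgrid[0:size, 0:size]
    t = np.deg2rad(tilt_deg)
    dx, dy = xs - cx, ys - cy
    u = dx * np.cos(t) + dy * np.sin(t)
    v = -dx * np.sin(t) + dy * np.cos(t)
    return (u / rx) ** 2 + (v / ry) ** 2 <= 1.0


def _render_instance(img, rng, cls_name: str, cx, cy, scale: float
                     ) -> np.ndarray:
    """Draw one blob; returns the instance's pixel mask."""
    size = img.shape[0]
    aspect, tilt, context = _GEOMETRY[cls_name]
    area = (scale * size / 7.0) ** 2
    ry = np.sqrt(area / aspect)
    rx = aspect * ry
    mask = _ellipse_mask(size, cx, cy, rx, ry, tilt)
    color = np.array(_BODY_COLOR[cls_name], dtype=np.float64)
    color = color + rng.normal(0, 4, 3)
    img[mask] = color
    # darker head disc at the ellipse tip
    t = np.deg2rad(tilt)
    hx, hy = cx + rx * 0.9 * np.cos(t), cy + rx * 0.9 * np.sin(t)
    head = _ellipse_mask(size, hx, hy, ry * 0.45, ry * 0.45, 0)
    img[head] = color * 0.75
    mask |= head
    if context == "legs":
        for sgn in (-1, 1):
            leg = _ellipse_mask(size, cx + sgn * rx * 0.5, cy + ry * 1.1,
                                ry * 0.18, ry * 0.5, 0)
            img[leg] = color * 0.85
            mask |= leg
    elif context == "trough":
        patch = _ellipse_mask(size, hx + ry * 0.5, hy, ry * 0.8, ry * 0.5, 0)
        img[patch] = (80, 52, 30)
        mask |= patch
    elif context == "nipple":
        patch = _ellipse_mask(size, hx + ry * 0.4, hy, ry * 0.35, ry * 0.35, 0)
        img[patch] = (60, 110, 225)
        mask |= patch
    return mask


def generate_scene(spec: SceneSpec
                   ) -> tuple[np.ndarray, list[BoxAnnotation]]:
    """Render one scene; bitwise deterministic for a fixed spec."""
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size
    img = _background(rng, size, spec.clutter)
    annots: list[BoxAnnotation] = []
    boxes_px: list[np.ndarray] = []

    order = [name for name in CLASS_NAMES
             for _ in range(spec.counts.get(name, 0))]
    for cls_name in order:
        placed = False
        for _ in range(200):
            scale = rng.uniform(0.85, 1.25)
            cx = rng.uniform(size * 0.15, size * 0.85)
            cy = rng.uniform(size * 0.15, size * 0.85)
            # probe extent before rendering
            aspect, tilt, _ = _GEOMETRY[cls_name]
            area = (scale * size / 7.0) ** 2
            ry = np.sqrt(area / aspect)
            rx = aspect * ry
            ext = max(rx, ry) * 1.6
            cand = np.array([cx - ext, cy - ext, cx + ext, cy + ext])
            from .evaluation import iou as _iou
            if all(_iou(cand, b) <= spec.occlusion for b in boxes_px):
                placed = True
                break
        if not placed:
            raise GenerationError(
                f"cannot place {cls_name!r} within occlusion bound "
                f"{spec.occlusion}")
        mask = _render_instance(img, rng, cls_name, cx, cy, scale)
        ys, xs = np.nonzero(mask)
        x1, x2 = xs.min(), xs.max() + 1
        y1, y2 = ys.min(), ys.max() + 1
        boxes_px.append(np.array([x1, y1, x2, y2], dtype=np.float64))
        annots.append(BoxAnnotation(
            CLASS_NAMES.index(cls_name),
            (x1 + x2) / 2 / size, (y1 + y2) / 2 / size,
            (x2 - x1) / size, (y2 - y1) / size))

    img *= BRIGHTNESS_REGIMES[spec.brightness_regime]
    return np.clip(img, 0, 255).astype(np.uint8), annots


def random_specs(n: int, seed: int, image_size: int = 128,
                 max_per_class: int = 2) -> list[SceneSpec]:
    """A seeded batch of scene specs with varied counts and regimes."""
    rng = np.random.default_rng(seed)
    specs = []
    regimes = list(BRIGHTNESS_REGIMES)
    for i in range(n):
        k = int(rng.integers(2, 5))
        chosen = rng.choice(len(CLASS_NAMES), size=k, replace=True)
        counts: dict[str, int] = {}
        for c in chosen:
            name = CLASS_NAMES[int(c)]
            counts[name] = min(counts.get(name, 0) + 1, max_per_class)
        specs.append(SceneSpec(
            image_size=image_size, counts=counts,
            occlusion=float(rng.uniform(0.15, 0.35)),
            brightness_regime=regimes[int(rng.integers(len(regimes)))],
            clutter=float(rng.uniform(0.1, 0.6)),
            seed=int(rng.integers(2 ** 31))))
    return specs


def generate_dataset(specs: list[SceneSpec], out_dir,
                     val_fraction: float = 0.0) -> Path:
    """Write images + YOLO-txt labels + dataset YAML; returns YAML path."""
    import imageio.v3 as iio

    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "labels").mkdir(parents=True, exist_ok=True)
    names = []
    for i, spec in enumerate(specs):
        img, annots = generate_scene(spec)
        stem = f"scene_{i:04d}"
        iio.imwrite(out / "images" / f"{stem}.png", img)
        write_yolo_labels(annots, out / "labels" / f"{stem}.txt")
        names.append(stem)
    n_val = int(round(val_fraction * len(names)))
    train_names = names[: len(names) - n_val] if n_val else names
    val_names = names[len(names) - n_val:] if n_val else names
    (out / "train.txt").write_text(
        "\n".join(f"images/{s}.png" for s in train_names) + "\n")
    (out / "val.txt").write_text(
        "\n".join(f"images/{s}.png" for s in val_names) + "\n")
    return write_dataset_yaml(out / "data.yaml", "train.txt", "val.txt")


def items_from_specs(specs: list[SceneSpec]) -> list[DatasetItem]:
    """In-memory dataset (no disk round-trip) for training and tests."""
    items = []
    for i, spec in enumerate(specs):
        img, annots = generate_scene(spec)
        items.append(DatasetItem(img, annots, name=f"scene_{i:04d}"))
    return items
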