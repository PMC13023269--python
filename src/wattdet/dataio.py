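"""Six-class behavior schema, YOLO-txt label I/O, class-targeted
augmentation, and grouped stratified splitting."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage

from .architecture import CLASS_NAMES
from .errors import ConfigurationError, ParseError, SchemaError

__all__ = [
    "BoxAnnotation", "AugmentationPlan", "DatasetItem",
    "read_yolo_labels", "write_yolo_labels",
    "hflip", "brightness", "motion_blur",
    "plan_augmentation", "execute_plan", "stratified_split",
    "load_dataset_yaml", "write_dataset_yaml", "class_counts",
]

NUM_CLASSES = len(CLASS_NAMES)

#: default per-class augmentation operations; motion blur targets the
#: fast-moving class only
DEFAULT_OPS = {name: ("hflip", "brightness") for name in CLASS_NAMES}
DEFAULT_OPS["walk"] = ("hflip", "brightness", "motion_blur")


@dataclass(frozen=True)
class BoxAnnotation:
    """Normalized centre-format box with one of six behavior classes."""

    class_id: int
    cx: float
    cy: float
    w: float
    h: float

    def __post_init__(self):
        if not 0 <= self.class_id < NUM_CLASSES:
            raise SchemaError(
                f"class_id {self.class_id} outside 0..{NUM_CLASSES - 1}")
        if self.w <= 0 or self.h <= 0:
            raise SchemaError(f"non-positive box size {self.w}x{self.h}")
        for v, name in ((self.cx, "cx"), (self.cy, "cy")):
            if not 0.0 <= v <= 1.0:
                raise SchemaError(f"{name}={v} outside [0, 1]")

    @property
    def class_name(self) -> str:
        return CLASS_NAMES[self.class_id]

    def clipped(self) -> "BoxAnnotation":
        """Clip the box so it lies fully inside the unit square."""
        if self.cx - self.w / 2 >= 0 and self.cx + self.w / 2 <= 1 \
                and self.cy - self.h / 2 >= 0 and self.cy + self.h / 2 <= 1:
            return self
        x1 = max(0.0, self.cx - self.w / 2)
        y1 = max(0.0, self.cy - self.h / 2)
        x2 = min(1.0, self.cx + self.w / 2)
        y2 = min(1.0, self.cy + self.h / 2)
        if x2 <= x1 or y2 <= y1:
            raise SchemaError("box clipped to nothing")
        return BoxAnnotation(self.class_id, (x1 + x2) / 2, (y1 + y2) / 2,
                             x2 - x1, y2 - y1)

    def corners(self, img_w: float = 1.0, img_h: float = 1.0) -> np.ndarray:
        return np.array([(self.cx - self.w / 2) * img_w,
                         (self.cy - self.h / 2) * img_h,
                         (self.cx + self.w / 2) * img_w,
                         (self.cy + self.h / 2) * img_h])


def read_yolo_labels(path) -> list[BoxAnnotation]:
    """Parse one ``class cx cy w h`` line per box; empty file = background.

    Rejects classes outside the schema and duplicate identical boxes
    carrying conflicting classes (mutually exclusive labeling).
    """
    annots: list[BoxAnnotation] = []
    text = Path(path).read_text()
    for ln, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 5:
            raise ParseError(f"expected 5 fields, got {len(parts)}", ln)
        try:
            cls = int(parts[0])
            vals = [float(v) for v in parts[1:]]
        except ValueError as e:
            raise ParseError(str(e), ln) from None
        a = BoxAnnotation(cls, *vals).clipped()
        for b in annots:
            same_box = (abs(a.cx - b.cx) < 1e-9 and abs(a.cy - b.cy) < 1e-9
                        and abs(a.w - b.w) < 1e-9 and abs(a.h - b.h) < 1e-9)
            if same_box and a.class_id != b.class_id:
                raise SchemaError(
                    f"line {ln}: identical box labeled both "
                    f"{b.class_name} and {a.class_name}")
        annots.append(a)
    return annots


def write_yolo_labels(annots: list[BoxAnnotation], path):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [f"{a.class_id} {a.cx:.6f} {a.cy:.6f} {a.w:.6f} {a.h:.6f}"
             for a in annots]
    path.write_text("\n".join(lines) + ("\n" if lines else ""))


# --------------------------------------------------------------------------
# augmentation primitives


def hflip(image: np.ndarray, annots: list[BoxAnnotation]
          ) -> tuple[np.ndarray, list[BoxAnnotation]]:
    """Mirror the image horizontally; cx -> 1 - cx, all else unchanged."""
    flipped = image[:, ::-1].copy()
    return flipped, [replace(a, cx=1.0 - a.cx) for a in annots]


def brightness(image: np.ndarray, factor: float) -> np.ndarray:
    """Scale intensities by ``factor`` and clip to the valid range."""
    if image.dtype == np.uint8:
        return np.clip(image.astype(np.float64) * factor, 0, 255) \
            .round().astype(np.uint8)
    return np.clip(image * factor, 0.0, 1.0)


def motion_blur(image: np.ndarray, kernel_len: int = 7,
                angle: float = 0.0) -> np.ndarray:
    """Directional mean filter; kernel is non-negative and sums to 1."""
    if kernel_len < 1:
        raise ConfigurationError("kernel_len must be >= 1")
    k = np.zeros((kernel_len, kernel_len))
    c = kernel_len // 2
    rad = np.deg2rad(angle)
    for t in np.linspace(-c, c, 4 * kernel_len):
        i = int(round(c + t * np.sin(rad)))
        j = int(round(c + t * np.cos(rad)))
        if 0 <= i < kernel_len and 0 <= j < kernel_len:
            k[i, j] = 1.0
    k /= k.sum()
    src = image.astype(np.float64)
    if src.ndim == 2:
        out = ndimage.convolve(src, k, mode="nearest")
    else:
        out = np.stack([ndimage.convolve(src[..., ch], k, mode="nearest")
                        for ch in range(src.shape[-1])], axis=-1)
    if image.dtype == np.uint8:
        return np.clip(out, 0, 255).round().astype(np.uint8)
    return np.clip(out, 0.0, 1.0)


# --------------------------------------------------------------------------
# plans and splits


@dataclass
class DatasetItem:
    """One image with its annotations and optional source-group key."""

    image: np.ndarray | None
    annots: list[BoxAnnotation]
    group: str | None = None
    name: str = ""


def class_counts(items: list[DatasetItem]) -> np.ndarray:
    counts = np.zeros(NUM_CLASSES, dtype=np.int64)
    for item in items:
        for a in item.annots:
            counts[a.class_id] += 1
    return counts


@dataclass
class AugmentationPlan:
    """Per-class instance targets and the operations used to reach them."""

    current: dict[str, int]
    targets: dict[str, int]
    ops: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_OPS))

    def __post_init__(self):
        for name in self.targets:
            if name not in CLASS_NAMES:
                raise SchemaError(f"unknown class {name!r}")
            cur = self.current.get(name, 0)
            if self.targets[name] < cur:
                raise ConfigurationError(
                    f"target for {name} ({self.targets[name]}) below "
                    f"current count ({cur})")

    @property
    def deficits(self) -> dict[str, int]:
        return {name: self.targets.get(name, 0) - self.current.get(name, 0)
                for name in self.targets}

    @property
    def empty(self) -> bool:
        return all(d == 0 for d in self.deficits.values())


def plan_augmentation(current_counts: dict[str, int],
                      targets: dict[str, int],
                      ops: dict[str, tuple[str, ...]] | None = None
                      ) -> AugmentationPlan:
    """Build a class-balancing plan from instance counts.

    Classes with larger deficits receive more synthesized samples; the
    operation set defaults to flip+brightness everywhere plus motion
    blur for the walk class.
    """
    plan = AugmentationPlan(dict(current_counts), dict(targets))
    if ops:
        plan.ops.update(ops)
    return plan


_OPS = {
    "hflip": lambda img, annots, rng: hflip(img, annots),
    "brightness": lambda img, annots, rng:
        (brightness(img, rng.uniform(0.6, 1.4)), annots),
    "motion_blur": lambda img, annots, rng:
        (motion_blur(img, 7, rng.uniform(0, 180)), annots),
}


def execute_plan(items: list[DatasetItem], plan: AugmentationPlan,
                 seed: int = 0) -> list[DatasetItem]:
    """Append augmented copies until every class deficit is met.

    Deterministic under ``seed``; each source image is sampled among
    those containing the deficient class and passed through that class's
    operation set.
    """
    rng = np.random.default_rng(seed)
    out = list(items)
    counts = {name: int(c) for name, c in
              zip(CLASS_NAMES, class_counts(items))}
    for name in CLASS_NAMES:
        target = plan.targets.get(name)
        if target is None:
            continue
        sources = [it for it in items
                   if any(a.class_name == name for a in it.annots)]
        if not sources and counts.get(name, 0) < target:
            raise ConfigurationError(
                f"no source image contains class {name!r}")
        k = 0
        while counts.get(name, 0) < target:
            src = sources[int(rng.integers(len(sources)))]
            img, annots = src.image, list(src.annots)
            for op in plan.ops.get(name, ()):
                img, annots = _OPS[op](img, annots, rng)
            out.append(DatasetItem(img, annots, group=src.group,
                                   name=f"{src.name}_aug{name}{k}"))
            for a in annots:
                counts[a.class_name] = counts.get(a.class_name, 0) + 1
            k += 1
    return out


def stratified_split(items: list[DatasetItem], ratio: float = 0.8,
                     seed: int = 0) -> tuple[list[DatasetItem],
                                             list[DatasetItem]]:
    """Grouped, class-balanced train/validation split.

    Items sharing a ``group`` key (e.g. frames of one video) never
    straddle the split.  Groups are assigned greedily in seeded random
    order so per-class instance proportions on each side track the
    requested ratio; deterministic under ``seed``.
    """
    if not 0.0 < ratio < 1.0:
        raise ConfigurationError("ratio must be in (0, 1)")
    rng = np.random.default_rng(seed)
    groups: dict[str, list[DatasetItem]] = {}
    for i, item in enumerate(items):
        key = item.group if item.group is not None else f"__item{i}"
        groups.setdefault(key, []).append(item)
    keys = sorted(groups)
    rng.shuffle(keys)
    n_train = int(round(ratio * len(keys)))
    train_keys, val_keys = [], []
    cls_train = np.zeros(NUM_CLASSES)
    cls_total = class_counts(items).astype(np.float64)
    for key in keys:
        g_counts = class_counts(groups[key]).astype(np.float64)
        if len(train_keys) >= n_train:
            val_keys.append(key)
            continue
        if len(val_keys) >= len(keys) - n_train:
            train_keys.append(key)
            cls_train += g_counts
            continue
        # assign where the running class balance deviates least
        with np.errstate(invalid="ignore", divide="ignore"):
            frac_if_train = np.where(
                cls_total > 0, (cls_train + g_counts) / cls_total, ratio)
            frac_if_val = np.where(
                cls_total > 0, cls_train / cls_total, ratio)
        dev_train = np.abs(frac_if_train - ratio).sum()
        dev_val = np.abs(frac_if_val - ratio).sum()
        if dev_train <= dev_val:
            train_keys.append(key)
            cls_train += g_counts
        else:
            val_keys.append(key)
    train = [it for k in train_keys for it in groups[k]]
    val = [it for k in val_keys for it in groups[k]]
    return train, val


# --------------------------------------------------------------------------
# dataset YAML


def write_dataset_yaml(path, train, val, names=CLASS_NAMES, groups=None):
    doc = {"names": list(names), "train": str(train), "val": str(val)}
    if groups:
        doc["groups"] = str(groups)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
    return Path(path)


def _resolve_images(root: Path, entry: str) -> list[Path]:
    p = (root / entry) if not Path(entry).is_absolute() else Path(entry)
    if p.is_dir():
        return sorted(q for q in p.iterdir()
                      if q.suffix.lower() in (".png", ".jpg", ".jpeg"))
    if p.suffix == ".txt":
        return [root / line.strip() if not Path(line.strip()).is_absolute()
                else Path(line.strip())
                for line in p.read_text().splitlines() if line.strip()]
    raise ConfigurationError(f"cannot resolve image source {entry!r}")


def load_dataset_yaml(path) -> dict:
    """Read a dataset YAML into {'names', 'train': [...], 'val': [...]}.

    Each split resolves to a list of ``DatasetItem`` with lazily loaded
    images (via imageio) and labels from the sibling ``labels`` tree.
    """
    import imageio.v3 as iio

    path = Path(path)
    doc = yaml.safe_load(path.read_text())
    root = path.parent
    group_map = {}
    if doc.get("groups"):
        gp = root / doc["groups"]
        for line in gp.read_text().splitlines():
            if line.strip():
                stem, grp = line.split()
                group_map[stem] = grp
    out = {"names": list(doc["names"])}
    for split in ("train", "val"):
        items = []
        for img_path in _resolve_images(root, doc[split]):
            lbl = img_path.parent.parent / "labels" / (img_path.stem + ".txt")
            annots = read_yolo_labels(lbl) if lbl.exists() else []
            items.append(DatasetItem(iio.imread(img_path), annots,
                                     group=group_map.get(img_path.stem),
                                     name=img_path.stem))
        out[split] = items
    return out
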