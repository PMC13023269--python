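"""Two-stage transfer-learning trainer.

Stage 1 freezes a prefix of the layer list and adapts the remainder at a
fixed learning rate; stage 2 unfreezes everything and fine-tunes under
cosine annealing.  Deterministic for a fixed seed on single-threaded
execution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .architecture import Detector
from .dataio import DatasetItem
from .errors import ConfigurationError
from .loss import detection_loss

__all__ = ["StageSchedule", "freeze_prefix", "unfreeze_all", "cosine_lr",
           "run_two_stage", "TrainLog"]


@dataclass
class StageSchedule:
    """Hyperparameters of the two training stages."""

    stage1_frozen_layers: int = 10
    stage1_lr: float = 2e-4
    stage1_epochs: int = 5
    stage2_lr0: float = 2e-4
    stage2_lr_final: float = 2e-6
    stage2_epochs: int = 50          # 150 selectable for the long schedule
    weight_decay: float = 5e-4
    batch_size: int = 4
    input_size: int = 640
    layer_lr_decay: float = 0.9      # per-stage-depth multiplicative factor
    dropout: float = 0.0             # detection heads rarely use it

    def __post_init__(self):
        if self.stage1_epochs < 0 or self.stage2_epochs < 0:
            raise ConfigurationError("epoch counts must be >= 0")
        if self.stage1_frozen_layers < 0:
            raise ConfigurationError("frozen layer count must be >= 0")

    @classmethod
    def long_schedule(cls) -> "StageSchedule":
        return cls(stage2_epochs=150)


def freeze_prefix(model: Detector, n_layers: int) -> Detector:
    """Exclude the first ``n_layers`` top-level layers from updates."""
    if n_layers > len(model.layers):
        raise ConfigurationError(
            f"cannot freeze {n_layers} of {len(model.layers)} layers")
    for i, layer in enumerate(model.layers):
        for p in layer.parameters():
            p.requires_grad = i >= n_layers
    return model


def unfreeze_all(model: Detector) -> Detector:
    for p in model.parameters():
        p.requires_grad = True
    return model


def cosine_lr(epoch: int, total_epochs: int, lr0: float,
              lr_final: float = 0.0) -> float:
    """lr(e) = lr_final + (lr0 - lr_final) * (1 + cos(pi e / E)) / 2."""
    if total_epochs <= 0:
        return lr0
    return lr_final + (lr0 - lr_final) \
        * (1.0 + math.cos(math.pi * epoch / total_epochs)) / 2.0


@dataclass
class TrainLog:
    """Per-epoch history rows (stage, lr, loss components, metrics)."""

    rows: list[dict] = field(default_factory=list)

    def append(self, **row):
        self.rows.append(row)

    def __len__(self):
        return len(self.rows)

    def to_csv(self, path):
        import csv
        from pathlib import Path
        keys = sorted({k for r in self.rows for k in r})
        with Path(path).open("w", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=keys)
            w.writeheader()
            for r in self.rows:
                w.writerow(r)


def _to_batch(items: list[DatasetItem], size: int) -> np.ndarray:
    imgs = []
    for it in items:
        img = it.image
        if img.ndim == 2:
            img = np.stack([img] * 3, axis=-1)
        if img.shape[0] != size or img.shape[1] != size:
            # nearest-neighbour square resize (desk-scale stand-in for
            # letterboxing; synthetic scenes are generated square)
            ys = (np.arange(size) * img.shape[0] / size).astype(int)
            xs = (np.arange(size) * img.shape[1] / size).astype(int)
            img = img[ys][:, xs]
        imgs.append(img.astype(np.float32).transpose(2, 0, 1) / 255.0)
    return np.stack(imgs)


def _layer_lr_mults(model: Detector, decay: float) -> list[float]:
    """Depth-hierarchical multipliers: shallower backbone stages decay
    more.  Stage depth runs P1..P5 over the backbone; neck and head use
    multiplier 1."""
    stage_of_layer = {0: 0, 1: 1, 2: 1, 3: 2, 4: 2, 5: 3, 6: 3, 7: 4,
                      8: 4, 9: 4, 10: 4}
    mults = []
    for i, layer in enumerate(model.layers):
        depth = stage_of_layer.get(i)
        m = decay ** (4 - depth) if depth is not None else 1.0
        mults.extend(m for p in layer.parameters())
    return mults


def run_two_stage(model: Detector, dataset: list[DatasetItem],
                  sched: StageSchedule | None = None, seed: int = 0,
                  iteration_cap: int | None = None,
                  log_every_iteration: bool = False
                  ) -> tuple[Detector, TrainLog]:
    """Execute stage 1 (frozen prefix) then stage 2 (cosine fine-tune).

    ``iteration_cap`` bounds the total number of optimizer steps (for
    desk-scale smoke runs); history holds one row per epoch regardless.
    """
    if not dataset:
        raise ConfigurationError("empty training split")
    sched = sched or StageSchedule()
    rng = np.random.default_rng(seed)
    log = TrainLog()
    steps = 0
    size = sched.input_size

    def run_stage(stage: int, epochs: int, lr_of_epoch, params):
        nonlocal steps
        mults = _layer_lr_mults(model, sched.layer_lr_decay) \
            if stage == 2 else None
        opt = nn.AdamW(params, lr=sched.stage1_lr,
                       weight_decay=sched.weight_decay)
        for epoch in range(epochs):
            if iteration_cap is not None and steps >= iteration_cap:
                break
            lr = lr_of_epoch(epoch)
            opt.lr = lr
            order = rng.permutation(len(dataset))
            epoch_losses = []
            for start in range(0, len(order), sched.batch_size):
                if iteration_cap is not None and steps >= iteration_cap:
                    break
                batch = [dataset[i] for i in
                         order[start:start + sched.batch_size]]
                x = nn.Tensor(_to_batch(batch, size))
                preds = model(x)
                loss, parts = detection_loss(
                    preds, [b.annots for b in batch], size,
                    num_classes=model.head.nc)
                if not np.isfinite(loss.data):
                    raise FloatingPointError(
                        f"NaN/Inf loss at stage {stage} epoch {epoch} "
                        f"step {steps}: {parts}")
                model.zero_grad()
                loss.backward()
                if mults is not None:
                    for p, m in zip(opt.params, mults):
                        if p.grad is not None and m != 1.0:
                            p.grad *= m
                opt.step()
                steps += 1
                epoch_losses.append(parts)
                if log_every_iteration:
                    log.append(stage=stage, epoch=epoch, iteration=steps,
                               lr=lr, **{f"loss_{k}": v
                                         for k, v in parts.items()})
            if not log_every_iteration:
                mean = {k: float(np.mean([e[k] for e in epoch_losses]))
                        for k in epoch_losses[0]} if epoch_losses else {}
                log.append(stage=stage, epoch=epoch, lr=lr,
                           **{f"loss_{k}": v for k, v in mean.items()})

    model.train()
    # stage 1: frozen backbone prefix, constant lr
    freeze_prefix(model, sched.stage1_frozen_layers)
    params1 = [p for p in model.parameters() if p.requires_grad]
    run_stage(1, sched.stage1_epochs, lambda e: sched.stage1_lr, params1)
    # stage 2: everything trainable, cosine schedule
    unfreeze_all(model)
    params2 = list(model.parameters())
    run_stage(2, sched.stage2_epochs,
              lambda e: cosine_lr(e, sched.stage2_epochs, sched.stage2_lr0,
                                  sched.stage2_lr_final), params2)
    model.eval()
    return model, log
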