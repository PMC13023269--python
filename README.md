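# wattdet

Lightweight six-class animal-behavior detection toolkit built around three
architectural modules on a nano-scale anchor-free detector:

* **SCSA** — channel + spatial attention with Sobel edge cues and
  cross-scale sharing of spatial gates between adjacent backbone stages
  (`wattdet.attention`);
* **WFU** — learnable softmax-normalized weighted fusion at every
  multi-branch neck node (`wattdet.fusion`);
* **WTConv** — 2-D discrete-wavelet-transform convolution that processes
  the four sub-bands independently and reconstructs with the inverse
  transform (`wattdet.wavelet`).

The detector (`wattdet.architecture`) is a C3k2/SPPF backbone with an
FPN-PAN neck and a decoupled distribution-focal head. All seven ablation
combinations of the three modules are exposed through `ModelConfig`
flags, with exact parameter/FLOP accounting (`count_params`,
`count_flops`).

Everything runs on a compact numpy reverse-mode autograd engine
(`wattdet.nn`) — no GPU and no deep-learning framework required. A seeded
synthetic scene generator (`wattdet.synthetic`) renders farm-like scenes
with exact YOLO-txt labels so training and evaluation are fully testable
at desk scale, offline.

Remaining pieces: YOLO-txt label I/O, class-targeted augmentation and
grouped stratified splitting (`wattdet.dataio`); a two-stage
transfer-learning trainer — frozen-prefix adaptation then cosine-annealed
joint fine-tuning (`wattdet.training`); and a detection metrics suite
with P/R/F1, AP, mAP@0.5, mAP@0.5:0.95, confusion matrices, PR curves and
gradient-based heatmaps (`wattdet.evaluation`).

## CLI

```bash
wattdet count --imgsz 640                     # parameter/FLOP budget table
wattdet build --cfg cfg.yaml --out model.npz  # build + save a detector
wattdet synth --n 64 --seed 7 --out fixtures/ # synthetic scenes + labels
wattdet split --data fixtures/data.yaml --ratio 0.8 --seed 17
wattdet augment --plan plan.yaml --seed 17 --out augmented/
wattdet train --cfg cfg.yaml --data fixtures/data.yaml --seed 17 \
              --imgsz 64 --out runs/train
wattdet eval --weights runs/train/model.npz --data fixtures/data.yaml \
             --out runs/eval
```

`cfg.yaml` holds `ModelConfig` fields, e.g.:

```yaml
use_scsa: true
use_wfu: true
use_wtconv: true
num_classes: 6
```

An augmentation plan names a dataset YAML and per-class instance targets:

```yaml
data: fixtures/data.yaml
targets: {walk: 7500, drink: 7500}
```

## Budget conventions

`count_params` counts trainable parameters. `count_flops` bills
2 FLOPs per convolution/linear multiply-accumulate plus 4 FLOPs per
batch-normalized element (unfused normalization performs two
multiply-adds per element); fixed-filter transforms (Sobel kernels, Haar
analysis/synthesis) are free. At a 640x640 input the baseline
configuration reports 2.59 M parameters / 6.4 GFLOPs and the full
three-module configuration 3.40 M / 7.8 GFLOPs.

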