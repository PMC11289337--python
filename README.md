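# valvedet

Lightweight single-stage detector for locating the **aortic valve** in
parasternal short-axis echocardiography frames, built for settings where
inference speed and model size matter as much as accuracy (point-of-care
ultrasound, embedded devices, high-throughput screening pipelines).

Echocardiography is the cheap, radiation-free modality for assessing aortic
stenosis, but valve assessment starts with finding the valve: a ring of three
leaflets, ~90–135 px across at 768-px frame size, embedded in speckle noise and
low contrast. `valvedet` re-builds the YOLOv5-s family of CSP/PANet detectors
as a *configurable block algebra* and then prunes it down to a ~150–190 k
parameter model by three moves:

1. **scale pruning** — dropping one of the three detection scales removes the
   widest neck stage and its prediction conv;
2. **depth-wise separable convolution** in the CSP bottlenecks — a spatial
   conv with cost `H·W·K²·Cin·Nconv` is replaced by a depth-wise + point-wise
   pair with cost `H·W·Cin·K² + H·W·Cin·Nconv`, an exact reduction factor of
   `1/Nconv + 1/K²`;
3. **K-means anchors** — Lloyd's algorithm on the dataset's ground-truth box
   (w, h) pairs replaces the generic anchor priors.

Because clinical echo data cannot be redistributed, the package ships a
deterministic synthetic-echo generator (sector mask, multiplicative Rayleigh
speckle, annulus + leaflet geometry in diastole/systole, optional
calcification) so training, anchor fitting and evaluation all run
self-contained.

## What's in the box

| module | contents |
|---|---|
| `valvedet.arch_config` | `ModelConfig` recipes, depth/width scaling rules, named presets |
| `valvedet.blocks` | CBL / DS-CBL / Focus / CSP1_X / CSP2_X / SPP / Detect: shape contracts, parameter & FLOP formulas, NumPy forward/backward |
| `valvedet.model_graph` | backbone + PANet neck assembly, scale pruning, decode, NMS, letterbox |
| `valvedet.complexity` | the analytic convolution cost model and whole-model profiling |
| `valvedet.anchor_gen` | Euclidean K-means anchor fitting and per-scale assignment |
| `valvedet.annotations_io` | YOLO txt / PASCAL-VOC XML, box normalization, IoU, dataset splitting |
| `valvedet.train_eval` | CIoU + objectness loss, SGD training loop, matching, P/R/F1/AP/mAP |
| `valvedet.synth_echo` | deterministic synthetic echocardiography fixtures |
| `valvedet.autodiff` | the small reverse-mode NumPy engine the network runs on |

## Worked example

```python
import valvedet as vd
from valvedet.complexity import cost_ratio, profile_model
from valvedet.model_graph import build_model

for name in ("baseline-s", "two-scale-s", "avd"):
    rep = profile_model(build_model(vd.get_preset(name), seed=0))
    print(f"{rep.name:12s} {rep.layers:4d} layers  {rep.parameters:>9,d} params  "
          f"{rep.gflops:5.1f} GFLOPs @ {rep.input_size}px")
print("DS/standard cost ratio, K=3, Nconv=16:", f"{cost_ratio(3, 16):.4f}")
```

prints

```
baseline-s    214 layers  7,022,326 params   15.8 GFLOPs @ 640px
two-scale-s   191 layers  5,240,036 params   14.3 GFLOPs @ 640px
avd           170 layers    186,620 params    0.7 GFLOPs @ 640px
DS/standard cost ratio, K=3, Nconv=16: 0.1736
```

`baseline-s` is the standard small three-scale model; `two-scale-s` drops the
stride-32 branch (23 fewer layers, 1.78 M fewer parameters); `avd` combines
two scales, 0.1 channel width and separable CSP convolutions. The cost ratio
`1/16 + 1/9 ≈ 0.17` is the per-block compute saving of the separable swap,
independent of resolution and input channels.

End-to-end on synthetic data:

```bash
valvedet synth --n 260 --seed 0 --out data/synth          # images + labels + data.yaml
valvedet anchors --labels data/synth/labels --img 768 --k 9 --seed 0
valvedet train --cfg avd --data data/synth/data.yaml --epochs 120 --img 256 --seed 0
valvedet val --cfg avd --weights runs/train/last.npz --data data/synth/data.yaml --iou 0.9
valvedet detect --cfg avd --weights runs/train/last.npz --source data/synth/images/test
```

`valvedet profile --cfg <preset>` reports any preset's layer/parameter/GFLOP
summary; `valvedet config show <preset>` dumps the resolved recipe as YAML.

## Caveats

The evaluation IoU threshold defaults to 0.9 — far stricter than the 0.5–0.7
conventional in detection benchmarks — so precision/recall numbers are not
comparable across thresholds. Timed inference (`valvedet profile --timed`) is
hardware-dependent and reported for information only. See `docs/methods.md`
for the model conventions, what the synthetic data does and does not emulate,
and known limitations.
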