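# Methods

This note records the model conventions, parameter choices and numerical
decisions behind `valvedet`, and what the synthetic-data experiments do and
do not demonstrate.

## Architecture family

Every model in the family is the same directed graph: a CSP backbone
(Focus stem → four stride-2 CBL stages, each followed by a CSP1_X block →
spatial pyramid pooling), a PANet neck (two top-down upsample/concat/CSP2
steps, two bottom-up stride-2 steps), and one 1×1 prediction conv per active
detection scale (P3/P4/P5 at strides 8/16/32, three anchors each, channels
`3·(5+nc)`).

Block composition is frozen as follows:

* **CBL** — conv (bias-free) → batch norm → leaky-ReLU (slope 0.1). A SiLU
  switch exists (`activation: silu`) for reconciliation experiments; the
  activation choice does not change parameter or FLOP counts.
* **CSP1_X / CSP2_X** — two parallel 1×1 CBL projections to half the output
  width `c_ = c_out/2`, a stack of X units on one path, concat, 1×1 CBL
  fusion. A CSP1 unit is a residual bottleneck (1×1 then 3×3 CBL at width
  `c_`, identity skip); a CSP2 unit is the same pair without the skip. At
  X = 1 the "X+1 CBLs" and "2X CBLs" readings of the CSP2 stack coincide,
  which is the regime every shipped preset lives in.
* **SPP** — 1×1 CBL to `c/2`, three parallel stride-1 max pools (5, 9, 13)
  concatenated with the unpooled branch, 1×1 CBL fusion from `2c`.
* **Detect** — per-scale 1×1 conv, the only biased conv, no BN.

**Scaling rules.** `depth_multiple` scales CSP repeat counts by
`max(round(n·d), 1)` with ties rounded half away from zero;
`width_multiple` scales channel widths rounded *up* to the nearest multiple
of 8. Configs store repeats post-scaling so a recipe is always an exact
description of the built graph.

**Layer counting.** The summary "layers" figure is the node count of the
fused module tree: model root and graph container, one node per block
wrapper, per convolution *stage*, per activation; a pooling stage, upsample
or concat counts once; the detect head counts its wrapper, branch list and
one node per branch. A depth-wise-separable stage counts the same as the
standard stage it replaces (it is one logical convolution). This convention
reproduces the published layer counts of the family exactly (214 for the
three-scale small model, 191 for two scales, 170 for the pruned lightweight
configuration), which is how it was calibrated and why it is frozen.

**Scale pruning.** The two-scale presets keep the stride-8 and stride-16
branches and drop the stride-32 tail (last bottom-up CBL, widest CSP2,
stride-32 prediction conv). Published layer/parameter deltas for the
two-scale model identify this tail unambiguously (Δ = 590,336 + 1,182,720 +
9,234 parameters at half width), even though scale removal is usually
narrated as dropping the *small-object* branch; the build routine simply
prunes whatever nodes feed no active prediction, so any subset of
{P3, P4, P5} is buildable. With two scales, nine anchor candidates are
truncated to the six largest by area.

**Depth-wise separable mode.** In `conv_mode: ds` the spatial (3×3) CBLs
inside CSP units become DS-CBL: depth-wise K×K conv → BN → point-wise 1×1
conv → BN → one trailing activation (MobileNet-style; 1×1 projections are
already point-wise and stay standard). This scope reproduces the published
GFLOP figure for the separable small model (11.2 at 640 px) but *not* its
published parameter count, and no systematic conversion scope or BN/bias
placement we searched reproduces both that count and the lightweight
model's; the separable parameter counts in this package (5,227,030 for
`dsconv-s`, 186,620 for `avd`) are therefore the honest outputs of the
stated composition, and the corresponding acceptance assertions against the
published figures fail by design rather than being tuned away.

## Cost model and profiling

`cost_conv = H·W·K²·Cin·Nconv` and `cost_dsconv = H·W·Cin·K² +
H·W·Cin·Nconv` count multiply-accumulates at the *output* resolution;
their ratio is exactly `1/Nconv + 1/K²` (available in exact rational
arithmetic). Whole-model GFLOPs are summed conv MACs × 2, profiled at
640 px by default (`--img` overrides); BN, activations and pooling are
excluded. This convention matches the family's published GFLOPs to ~2%,
the spread the published figures themselves show. Latency is measured only
on request (median of ≥50 runs after warm-up) and is host-dependent.

## Anchors

K-means on raw (w, h) pixel pairs with Euclidean distance (not the
IoU-distance variant used elsewhere in the detection literature), Lloyd
iteration to `tol = 1e-4` px or `max_iter = 300`, initial centres drawn
uniformly from the data. Plain random initialisation is prone to local
optima that split one size mode and merge others, so `n_init = 50` restarts
are run and the lowest within-cluster sum of squares kept; an emptied
cluster is re-seeded from the point farthest from any centre. Centres are
rounded to integer pixels, sorted by area, chunked into triples, and the
smallest triple assigned to the smallest-stride (highest-resolution) active
scale. Anchors are pixels at a stated reference size and rescale linearly
with the model input size.

## Annotation geometry

Image coordinates have the origin at the top-left corner, y down; (x1, y1)
is the min corner. The normalized record is `class cx cy w h` with
`cx = ((x1+x2)/2)/w` etc.; encode/decode are exact algebraic inverses
(round-trip error ~1e-13 px in float64). Label files carry one record per
line at 6 decimals; class ids are 0-based with the single class
`aortic_valve = 0`. PASCAL-VOC XML (`xmin/ymin/xmax/ymax`) converts through
the same arithmetic. Dataset splitting floors the val/test fractions and
gives the remainder to train, so 260 items at 80/5/15 split (208, 13, 39),
deterministically under a seed.

## Training

SGD with momentum 0.937, weight decay 5e-4 (applied to conv weights only,
not BN/bias), constant learning rate 0.01, batch size 16, 768-px inputs,
500 epochs — the family's standard recipe; the loss is scaled by the batch
size, as is conventional for this family, so gradient magnitudes are
batch-size-invariant per image. Augmentation is horizontal flip only
(p = 0.5). Targets: a ground-truth box is assigned to every
(scale, anchor) whose width/height ratio test `max(w/aw, aw/w, h/ah, ah/h)
< 4` passes, at the cell containing its centre; if nothing passes, the
best-ratio anchor is forced. Box loss is `1 − CIoU` averaged over
positives (the CIoU aspect term's α is treated as a constant in the
gradient, the standard treatment); objectness is binary cross-entropy over
every cell with CIoU-scaled positive targets, balanced 4.0/1.0/0.4 across
strides 8/16/32. With one class the classification loss is omitted;
decoded confidence is `σ(obj)·σ(cls)` per the head contract, which for a
single class is a near-constant rescaling of objectness. Training is
bitwise deterministic on CPU for a fixed seed (weight init, shuffling and
flips all draw from one seeded generator).

## Evaluation

Detections are decoded (`centre = (2σ(t_xy) − 0.5 + cell)·stride`,
`size = (2σ(t_wh))²·anchor`), NMS-filtered (greedy by descending
confidence, stable tie-break on input order), then matched to ground truth
greedily by confidence: a detection is TP iff its best-IoU unmatched
ground truth reaches the threshold. AP integrates the right-max precision
envelope over recall (all-point interpolation — the integral definition,
verified against brute-force envelope integration for every TP/FP pattern
of length ≤ 8); with one class mAP = AP. The headline operating threshold
is IoU 0.9; evaluation at 0.5 is also reported since the two are not
comparable. Zero-denominator metrics are reported as 0 with a
`degenerate` flag.

## Synthetic data

The generator emulates the first-order appearance of parasternal
short-axis frames: an ultrasound sector on a dark background, a smooth
tissue intensity field, multiplicative speckle (Rayleigh field, lightly
smoothed, unit mean — zero tissue stays zero), and one bright elliptical
annulus whose tight bounding box is the ground truth. Diastole renders
three leaflet chords meeting centrally; systole renders a darker central
triangular orifice with bright commissural edges; the calcific variant
adds 1–3 bright blobs on the ring. Box sides default to uniform
[88, 134] px at 768 px — the span of the fitted anchor priors — or to
explicit (w, h) modes ± 3 px when cluster-recovery experiments need
multi-modal sizes. Everything is bit-reproducible given (seed, index).

What it does **not** emulate: acoustic shadowing, depth-dependent
attenuation and focus, motion blur, neighbouring anatomy (LVOT, right
ventricle, pericardium), probe-dependent speckle statistics, or multiple
competing ring-like structures. Tests passing on this data show the
pipeline is correct and trainable, not that the detector generalises to
clinical echo.

**Problem sizes in the test suite.** The end-to-end check trains the
lightweight preset on an 8-frame fixture at 192-px input (anchors rescale
accordingly) and verifies memorisation to train mAP@0.5 ≥ 0.9 within 120
epochs of plain SGD — a capacity/optimisation sanity run, chosen at a
scale where the full NumPy forward/backward completes in about a minute.
Anchor recovery uses a 260-frame corpus at full 768-px size with three
planted size modes. A larger train/held-out generalisation run (e.g. 64/16
frames) is supported by the same API (`build_dataset`, `train`,
`evaluate`) for users who want it.

## Numerical choices

float32 throughout the network; BN eps 1e-5, momentum 0.1 on running
stats; CIoU/IoU eps 1e-7; BCE computed on sigmoids clamped to
[1e-7, 1−1e-7]; detect conv weights initialised small (σ = 0.01) with
objectness biases set so initial foreground probability is low; all other
convs He-initialised. Greedy NMS and matching break confidence ties by
input order. Degenerate inputs (empty detection lists, empty label files,
images with no objects) are defined no-ops rather than errors, except
where a quantity is undefined (recall with zero ground truth raises).

## Known limitations

* The NumPy engine is CPU-only and single-threaded beyond BLAS; full-scale
  768-px training is possible but slow — the package's training claims are
  demonstrated at reduced input sizes.
* mAP is computed single-class; the multi-class path (per-class AP
  averaging) is implemented but untested beyond nc = 1.
* Letterboxing uses bilinear resize via Pillow; sub-pixel box accuracy
  after inverse mapping is limited by that interpolation.
* The separable-variant parameter counts differ from some published
  figures for this family, as detailed above; the discrepancy is
  documented rather than reconciled because no consistent block
  composition reproduces them.
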