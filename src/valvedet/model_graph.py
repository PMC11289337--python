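"""Assembly of the full detector graph and its inference post-processing.

The graph is the CSP backbone (Focus stem, four strided CBL/CSP1
stages, spatial pyramid pooling), a PANet neck (two top-down
upsample/concat/CSP2 steps, two bottom-up stride-2 steps) and one 1x1
prediction conv per active detection scale.  Scales are named by their
stride: P3 (stride 8), P4 (stride 16), P5 (stride 32).

When a scale is dropped from ``active_scales`` the nodes that feed only
that scale's prediction are pruned from the graph, so the pruned model
really is smaller — dropping P5 removes the final bottom-up CBL, the
widest CSP2 block and the stride-32 prediction conv.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .arch_config import ModelConfig, SCALE_STRIDES
from .autodiff import Tensor
from .blocks import (BlockError, ConvBNAct, CSP, Concat, DetectBranch, Focus,
                     Module, SPP, Shape, Upsample, block_layer_count,
                     csp_flops, csp_param_count, _conv_p, _conv_f)
from .annotations_io import BBox, iou as box_iou

__all__ = ["Model", "Detection", "build_model", "decode_predictions", "nms",
           "letterbox"]

NA = 3  # anchors per detection scale


@dataclass(frozen=True)
class Detection:
    """One scored prediction in input-image pixel coordinates."""

    bbox: BBox
    confidence: float
    class_id: int = 0

    def __post_init__(self):
        if not (0.0 <= self.confidence <= 1.0):
            raise BlockError(f"confidence {self.confidence} outside [0, 1]")


@dataclass
class _Node:
    name: str
    kind: str
    module: Module
    src: tuple          # indices of input nodes (-0 == image input for node 0)
    ci: int
    co: int
    kernel: int = 1
    stride: int = 1
    repeats: int = 1
    ds: bool = False


class Model(Module):
    """Built detector: ordered node list + per-scale prediction convs."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        self.num_classes = config.num_classes
        act = config.activation
        mode = config.conv_mode
        cs, c2, c3, c4, c5 = config.stage_channels()
        self.nodes: list[_Node] = []
        n = self._add

        # backbone
        n("stem", "focus", Focus(3, cs, 3, rng, act), (), 3, cs, kernel=3)
        n("b1", "cbl", ConvBNAct(cs, c2, 3, 2, rng, act=act), (0,), cs, c2, 3, 2)
        n("b2", "csp1", CSP(c2, c2, config.backbone_repeats[0], rng, True, mode, act),
          (1,), c2, c2, repeats=config.backbone_repeats[0], ds=mode == "ds")
        n("b3", "cbl", ConvBNAct(c2, c3, 3, 2, rng, act=act), (2,), c2, c3, 3, 2)
        n("b4", "csp1", CSP(c3, c3, config.backbone_repeats[1], rng, True, mode, act),
          (3,), c3, c3, repeats=config.backbone_repeats[1], ds=mode == "ds")
        n("b5", "cbl", ConvBNAct(c3, c4, 3, 2, rng, act=act), (4,), c3, c4, 3, 2)
        n("b6", "csp1", CSP(c4, c4, config.backbone_repeats[2], rng, True, mode, act),
          (5,), c4, c4, repeats=config.backbone_repeats[2], ds=mode == "ds")
        n("b7", "cbl", ConvBNAct(c4, c5, 3, 2, rng, act=act), (6,), c4, c5, 3, 2)
        n("b8", "csp1", CSP(c5, c5, config.backbone_repeats[3], rng, True, mode, act),
          (7,), c5, c5, repeats=config.backbone_repeats[3], ds=mode == "ds")
        n("b9", "spp", SPP(c5, c5, rng=rng, act=act), (8,), c5, c5)

        # neck: top-down
        n("n10", "cbl", ConvBNAct(c5, c4, 1, 1, rng, act=act), (9,), c5, c4)
        n("n11", "upsample", Upsample(), (10,), c4, c4)
        n("n12", "concat", Concat(), (11, 6), 2 * c4, 2 * c4)
        n("n13", "csp2", CSP(2 * c4, c4, config.neck_repeats[0], rng, False, mode, act),
          (12,), 2 * c4, c4, repeats=config.neck_repeats[0], ds=mode == "ds")
        n("n14", "cbl", ConvBNAct(c4, c3, 1, 1, rng, act=act), (13,), c4, c3)
        n("n15", "upsample", Upsample(), (14,), c3, c3)
        n("n16", "concat", Concat(), (15, 4), 2 * c3, 2 * c3)
        n("n17", "csp2", CSP(2 * c3, c3, config.neck_repeats[1], rng, False, mode, act),
          (16,), 2 * c3, c3, repeats=config.neck_repeats[1], ds=mode == "ds")

        # neck: bottom-up
        n("n18", "cbl", ConvBNAct(c3, c3, 3, 2, rng, act=act), (17,), c3, c3, 3, 2)
        n("n19", "concat", Concat(), (18, 14), 2 * c3, 2 * c3)
        n("n20", "csp2", CSP(2 * c3, c4, config.neck_repeats[2], rng, False, mode, act),
          (19,), 2 * c3, c4, repeats=config.neck_repeats[2], ds=mode == "ds")
        n("n21", "cbl", ConvBNAct(c4, c4, 3, 2, rng, act=act), (20,), c4, c4, 3, 2)
        n("n22", "concat", Concat(), (21, 10), 2 * c4, 2 * c4)
        n("n23", "csp2", CSP(2 * c4, c5, config.neck_repeats[3], rng, False, mode, act),
          (22,), 2 * c4, c5, repeats=config.neck_repeats[3], ds=mode == "ds")

        feature_of = {"P3": 17, "P4": 20, "P5": 23}
        self.scales = sorted(config.active_scales, key=SCALE_STRIDES.get)
        self.strides = [SCALE_STRIDES[s] for s in self.scales]

        # prune nodes that feed no active prediction branch
        needed = set()
        stack = [feature_of[s] for s in self.scales]
        while stack:
            i = stack.pop()
            if i in needed:
                continue
            needed.add(i)
            stack.extend(self.nodes[i].src)
        self.keep = sorted(needed)
        for i, node in enumerate(self.nodes):
            if i not in needed:
                del self._children[node.name]
        self.nodes = [nd for i, nd in enumerate(self.nodes) if i in needed]
        remap = {old: new for new, old in enumerate(self.keep)}
        for nd in self.nodes:
            nd.src = tuple(remap[s] for s in nd.src)
        self.feature_idx = [remap[feature_of[s]] for s in self.scales]

        self.det = [self.add_child(f"det_{s}",
                                   DetectBranch(self.nodes[fi].co, NA,
                                                config.num_classes, rng,
                                                stride=SCALE_STRIDES[s]))
                    for s, fi in zip(self.scales, self.feature_idx)]
        self.input_size = config.input_size
        self.anchors = self._resolve_anchors()

    def _add(self, name, kind, module, src, ci, co, kernel=1, stride=1,
             repeats=1, ds=False):
        self.add_child(name, module)
        self.nodes.append(_Node(name, kind, module, src, ci, co, kernel,
                                stride, repeats, ds))

    def _resolve_anchors(self) -> dict:
        from .anchor_gen import assign_anchors
        ref = self.config.anchor_reference or self.config.input_size
        scale = self.config.input_size / ref
        scaled = [(w * scale, h * scale) for w, h in self.config.anchors]
        return assign_anchors(scaled, self.scales)

    # -- summaries ------------------------------------------------------

    def layer_count(self) -> int:
        total = 2  # model wrapper + sequential graph
        for nd in self.nodes:
            total += block_layer_count(nd.kind, nd.repeats)
        total += 2 + len(self.det)  # detect wrapper + branch list + convs
        return total

    def parameter_count(self) -> int:
        """Analytic parameter total (equals brute-force array enumeration)."""
        total = 0
        for nd in self.nodes:
            if nd.kind == "focus":
                total += _conv_p(4 * nd.ci, nd.co, nd.kernel)
            elif nd.kind == "cbl":
                total += _conv_p(nd.ci, nd.co, nd.kernel)
            elif nd.kind in ("csp1", "csp2"):
                total += csp_param_count(nd.ci, nd.co, nd.repeats, nd.ds)
            elif nd.kind == "spp":
                total += _conv_p(nd.ci, nd.ci // 2, 1) + _conv_p(2 * nd.ci, nd.co, 1)
        for d, fi in zip(self.det, self.feature_idx):
            total += (self.nodes[fi].co + 1) * NA * (5 + self.num_classes)
        return total

    def flop_count(self, input_size: int | None = None) -> int:
        """Convolution multiply-accumulates of one forward pass."""
        size = input_size or self.input_size
        if size % 32:
            raise BlockError(f"input size {size} not a multiple of 32")
        hw = {}  # node index -> spatial size
        total = 0
        for i, nd in enumerate(self.nodes):
            s_in = size if not nd.src else hw[nd.src[0]]
            s_out = s_in // 2 if (nd.stride == 2 or nd.kind == "focus") else s_in
            hw[i] = s_out
            h = w = s_out
            if nd.kind == "focus":
                total += _conv_f(h, w, 4 * nd.ci, nd.co, nd.kernel)
            elif nd.kind == "cbl":
                total += _conv_f(h, w, nd.ci, nd.co, nd.kernel)
            elif nd.kind in ("csp1", "csp2"):
                total += csp_flops(h, w, nd.ci, nd.co, nd.repeats, nd.ds)
            elif nd.kind == "spp":
                total += (_conv_f(h, w, nd.ci, nd.ci // 2, 1)
                          + _conv_f(h, w, 2 * nd.ci, nd.co, 1))
            elif nd.kind == "upsample":
                hw[i] = s_in * 2
        for fi in self.feature_idx:
            h = w = hw[fi]
            total += _conv_f(h, w, self.nodes[fi].co, NA * (5 + self.num_classes), 1)
        return total

    # -- forward --------------------------------------------------------

    def forward(self, images) -> list:
        """Run a batch through the graph; one raw grid per active scale.

        ``images``: (N, 3, H, W) array (or Tensor), H and W multiples of
        32.  Returns Tensors of shape (N, na*(5+nc), H/stride, W/stride)
        ordered fine-to-coarse.
        """
        x = images if isinstance(images, Tensor) else Tensor(images)
        if x.ndim != 4 or x.shape[1] != 3:
            raise BlockError(f"expected (N, 3, H, W) input, got {x.shape}")
        if x.shape[2] % 32 or x.shape[3] % 32:
            raise BlockError("input spatial dims must be multiples of 32")
        outs = []
        for nd in self.nodes:
            if not nd.src:
                y = nd.module(x)
            elif nd.kind == "concat":
                y = nd.module([outs[s] for s in nd.src])
            else:
                y = nd.module(outs[nd.src[0]])
            outs.append(y)
        return [d(outs[fi]) for d, fi in zip(self.det, self.feature_idx)]

    __call__ = forward


def build_model(config: ModelConfig, seed: int = 0) -> Model:
    """Instantiate a detector with freshly initialised weights."""
    config.validate()
    return Model(config, np.random.default_rng(seed))


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def decode_predictions(grids, anchors: dict, strides, conf_threshold: float,
                       num_classes: int = 1) -> list:
    """Decode raw grids into per-image :class:`Detection` lists.

    Per cell and anchor: centre = (2*sigma(t_xy) - 0.5 + cell) * stride,
    size = (2*sigma(t_wh))^2 * anchor, confidence = sigma(t_obj) *
    max-class sigma(t_cls).
    """
    scales = list(anchors)
    if len(grids) != len(scales) or len(strides) != len(scales):
        raise BlockError("grid/anchor/stride count mismatch")
    n_img = grids[0].shape[0] if hasattr(grids[0], "shape") else len(grids[0])
    results = [[] for _ in range(n_img)]
    for grid, scale, stride in zip(grids, scales, strides):
        g = grid.data if isinstance(grid, Tensor) else np.asarray(grid)
        anc = np.asarray(anchors[scale], dtype=np.float64)
        if anc.shape[0] != NA:
            raise BlockError(f"scale {scale}: expected {NA} anchors, got {anc.shape[0]}")
        n, ch, h, w = g.shape
        if ch != NA * (5 + num_classes):
            raise BlockError(f"grid channels {ch} != {NA * (5 + num_classes)}")
        g = g.reshape(n, NA, 5 + num_classes, h, w)
        sig = _sigmoid(g)
        ys, xs = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        cx = (2 * sig[:, :, 0] - 0.5 + xs) * stride
        cy = (2 * sig[:, :, 1] - 0.5 + ys) * stride
        bw = (2 * sig[:, :, 2]) ** 2 * anc[:, 0].reshape(1, NA, 1, 1)
        bh = (2 * sig[:, :, 3]) ** 2 * anc[:, 1].reshape(1, NA, 1, 1)
        cls_p = sig[:, :, 5:]
        conf = sig[:, :, 4] * cls_p.max(axis=2)
        cls_id = cls_p.argmax(axis=2)
        keep = conf >= conf_threshold
        for bi in range(n):
            for ai, yi, xi in zip(*np.nonzero(keep[bi])):
                wv, hv = bw[bi, ai, yi, xi], bh[bi, ai, yi, xi]
                if wv <= 0 or hv <= 0:
                    continue
                box = BBox(cx[bi, ai, yi, xi] - wv / 2, cy[bi, ai, yi, xi] - hv / 2,
                           cx[bi, ai, yi, xi] + wv / 2, cy[bi, ai, yi, xi] + hv / 2)
                results[bi].append(Detection(box, float(conf[bi, ai, yi, xi]),
                                             int(cls_id[bi, ai, yi, xi])))
    for r in results:
        r.sort(key=lambda d: -d.confidence)
    return results


def nms(detections: list, iou_threshold: float) -> list:
    """Greedy non-maximum suppression by descending confidence (stable)."""
    order = sorted(range(len(detections)),
                   key=lambda i: (-detections[i].confidence, i))
    kept: list = []
    for i in order:
        d = detections[i]
        if all(k.class_id != d.class_id or box_iou(k.bbox, d.bbox) <= iou_threshold
               for k in kept):
            kept.append(d)
    return kept


def letterbox(img: np.ndarray, size: int, pad_value: int = 114):
    """Aspect-preserving resize onto a size x size gray canvas.

    Returns ``(canvas, scale, (dx, dy))`` so that an original-image
    coordinate p maps to ``p * scale + (dx, dy)`` on the canvas.
    ``img`` is (H, W) grayscale or (H, W, 3).
    """
    from PIL import Image

    h, w = img.shape[:2]
    scale = min(size / h, size / w)
    nh, nw = max(int(round(h * scale)), 1), max(int(round(w * scale)), 1)
    pil = Image.fromarray(img)
    resized = np.asarray(pil.resize((nw, nh), Image.BILINEAR))
    if img.ndim == 2:
        canvas = np.full((size, size), pad_value, dtype=img.dtype)
    else:
        canvas = np.full((size, size, img.shape[2]), pad_value, dtype=img.dtype)
    dy, dx = (size - nh) // 2, (size - nw) // 2
    canvas[dy:dy + nh, dx:dx + nw] = resized
    return canvas, scale, (dx, dy)
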