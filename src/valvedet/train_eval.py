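"""Loss, SGD training loop, detection matching and the metric suite.

Training follows the detector family's standard recipe: SGD with
momentum 0.937, weight decay 5e-4 and learning rate 0.01 (constant),
batch size 16, 768-px inputs, 500 epochs; augmentation is horizontal
flip only.  With a single object class the classification loss term is
omitted and the prediction confidence is carried by the objectness
channel.

Evaluation matches detections to ground truth greedily by descending
confidence at a configurable IoU threshold (0.9 for the headline
comparisons; 0.5 for the conventional operating point), builds the
cumulative precision/recall curve, and integrates the right-max
precision envelope over recall for AP.  With one class, mAP equals AP.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .annotations_io import BBox, NormalizedBox, decode_yolo_box, iou as box_iou
from .autodiff import Tensor, SGD
from .model_graph import Model, NA, decode_predictions, nms

__all__ = [
    "Hyperparams", "MatchResult", "MetricsReport", "DetectionDataset",
    "bce_with_logits", "compute_loss", "train", "evaluate",
    "match_detections", "pr_curve", "average_precision", "metrics_report",
    "save_weights", "load_weights",
]

#: per-scale objectness balance, fine-to-coarse (stride 8, 16, 32)
OBJ_BALANCE = {8: 4.0, 16: 1.0, 32: 0.4}
ANCHOR_RATIO_LIMIT = 4.0


@dataclass
class Hyperparams:
    epochs: int = 500
    batch_size: int = 16
    input_size: int = 768
    momentum: float = 0.937
    weight_decay: float = 0.0005
    learning_rate: float = 0.01
    eval_iou_threshold: float = 0.9
    seed: int = 0
    box_gain: float = 0.05
    obj_gain: float = 1.0
    flip_prob: float = 0.5

    def __post_init__(self):
        if min(self.epochs, self.batch_size, self.input_size) < 1:
            raise ValueError("epochs, batch_size and input_size must be positive")
        if not (0.0 < self.eval_iou_threshold <= 1.0):
            raise ValueError("eval_iou_threshold must be in (0, 1]")
        if self.learning_rate <= 0 or self.momentum < 0 or self.weight_decay < 0:
            raise ValueError("invalid optimiser hyperparameters")


@dataclass
class DetectionDataset:
    """In-memory dataset: samples are (image, boxes) pairs.

    ``images`` are uint8 arrays, (H, W) grayscale or (H, W, 3); boxes
    are :class:`NormalizedBox` lists.  ``splits`` maps split names to
    index lists.
    """

    images: list
    labels: list
    splits: dict = field(default_factory=dict)
    class_names: tuple = ("aortic_valve",)

    def __len__(self):
        return len(self.images)

    def subset(self, split: str) -> "DetectionDataset":
        idx = self.splits[split]
        return DetectionDataset([self.images[i] for i in idx],
                                [self.labels[i] for i in idx],
                                {}, self.class_names)

    @classmethod
    def from_data_yaml(cls, path) -> "DetectionDataset":
        """Load a YOLO-layout dataset described by a data.yaml file."""
        import yaml
        from PIL import Image

        from .annotations_io import read_label_file

        path = Path(path)
        doc = yaml.safe_load(path.read_text())
        root = Path(doc.get("path", path.parent))
        if not root.is_absolute():
            root = path.parent / root
        images, labels, splits = [], [], {}
        for split in ("train", "val", "test"):
            if split not in doc:
                continue
            img_dir = root / doc[split]
            lbl_dir = Path(str(img_dir).replace("images", "labels", 1))
            idxs = []
            for img_path in sorted(img_dir.glob("*")):
                if img_path.suffix.lower() not in (".png", ".jpg", ".jpeg"):
                    continue
                lbl = lbl_dir / (img_path.stem + ".txt")
                images.append(np.asarray(Image.open(img_path)))
                labels.append(read_label_file(lbl) if lbl.exists() else [])
                idxs.append(len(images) - 1)
            splits[split] = idxs
        return cls(images, labels, splits,
                   tuple(doc.get("names", ("aortic_valve",))))


def _to_batch(images, size: int) -> np.ndarray:
    """Stack uint8 images into a float32 (N, 3, size, size) batch."""
    out = np.empty((len(images), 3, size, size), dtype=np.float32)
    for i, img in enumerate(images):
        if img.shape[:2] != (size, size):
            raise ValueError(f"image {i} is {img.shape[:2]}, expected {(size, size)}")
        a = img.astype(np.float32) / 255.0
        out[i] = a.transpose(2, 0, 1) if a.ndim == 3 else a[None].repeat(3, axis=0)
    return out


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Elementwise binary cross-entropy on logits (mean-free)."""
    s = logits.sigmoid().clamp(1e-7, 1.0 - 1e-7)
    t = Tensor(targets)
    return -(t * s.log() + (1.0 - t) * (1.0 - s).log())


def _build_targets(targets_per_image, model: Model):
    """Anchor assignment: one positive per (gt, scale, fitting anchor).

    An anchor fits when max(w/aw, aw/w, h/ah, ah/h) < 4.  If nothing
    fits anywhere, the globally best-ratio anchor is forced positive.
    """
    size = model.input_size
    assigned = {si: [] for si in range(len(model.scales))}
    for bi, boxes in enumerate(targets_per_image):
        for nb in boxes:
            gw, gh = nb.w * size, nb.h * size
            best, best_ratio = None, np.inf
            any_hit = False
            for si, (scale, stride) in enumerate(zip(model.scales, model.strides)):
                g = size // stride
                gx, gy = nb.cx * size / stride, nb.cy * size / stride
                cx, cy = min(int(gx), g - 1), min(int(gy), g - 1)
                for ai, (aw, ah) in enumerate(model.anchors[scale]):
                    r = max(gw / aw, aw / gw, gh / ah, ah / gh)
                    entry = (bi, ai, cy, cx, gx - cx, gy - cy, gw, gh, aw, ah)
                    if r < ANCHOR_RATIO_LIMIT:
                        assigned[si].append(entry)
                        any_hit = True
                    if r < best_ratio:
                        best_ratio, best = r, (si, entry)
            if not any_hit and best is not None:
                assigned[best[0]].append(best[1])
    return assigned


def _ciou(px, py, pw, ph, tx, ty, tw, th):
    """Differentiable complete-IoU between centre-form box tensors."""
    eps = 1e-7
    p_x1, p_x2 = px - pw * 0.5, px + pw * 0.5
    p_y1, p_y2 = py - ph * 0.5, py + ph * 0.5
    t_x1, t_x2 = tx - tw * 0.5, tx + tw * 0.5
    t_y1, t_y2 = ty - th * 0.5, ty + th * 0.5
    iw = p_x2.minimum(t_x2) - p_x1.maximum(t_x1)
    ih = p_y2.minimum(t_y2) - p_y1.maximum(t_y1)
    inter = iw.clamp(0.0, None) * ih.clamp(0.0, None)
    union = pw * ph + tw * th - inter + eps
    iou = inter / union
    cw = p_x2.maximum(t_x2) - p_x1.minimum(t_x1)
    ch = p_y2.maximum(t_y2) - p_y1.minimum(t_y1)
    c2 = cw * cw + ch * ch + eps
    rho2 = (px - tx) * (px - tx) + (py - ty) * (py - ty)
    v = (tw / th).atan() - (pw / ph).atan()
    v = v * v * (4.0 / math.pi ** 2)
    alpha = Tensor(v.data / (1.0 - iou.data + v.data + eps))  # no grad through alpha
    return iou - rho2 / c2 - alpha * v


def compute_loss(grids, targets_per_image, model: Model, hp: Hyperparams):
    """(box_loss, objectness_loss, total) for one forward pass.

    Box loss is mean(1 - CIoU) over assigned positives; objectness is
    BCE over every cell with CIoU-scaled positive targets, balanced
    per scale.  The classification term is omitted for one class.
    """
    nc = model.num_classes
    assigned = _build_targets(targets_per_image, model)
    box_terms, obj_loss = [], None
    n_pos_total = 0
    for si, (grid, stride) in enumerate(zip(grids, model.strides)):
        n, ch, h, w = grid.shape
        g5 = grid.reshape(n, NA, 5 + nc, h, w)
        obj_t = np.zeros((n, NA, h, w), dtype=np.float32)
        pos = assigned[si]
        if pos:
            n_pos_total += len(pos)
            bi = np.array([p[0] for p in pos])
            ai = np.array([p[1] for p in pos])
            cy = np.array([p[2] for p in pos])
            cx = np.array([p[3] for p in pos])
            ox = np.array([p[4] for p in pos], dtype=np.float32)
            oy = np.array([p[5] for p in pos], dtype=np.float32)
            tw = np.array([p[6] for p in pos], dtype=np.float32)
            th = np.array([p[7] for p in pos], dtype=np.float32)
            aw = np.array([p[8] for p in pos], dtype=np.float32)
            ah = np.array([p[9] for p in pos], dtype=np.float32)
            tx_ = g5.gather_nd((bi, ai, np.full_like(bi, 0), cy, cx))
            ty_ = g5.gather_nd((bi, ai, np.full_like(bi, 1), cy, cx))
            tw_ = g5.gather_nd((bi, ai, np.full_like(bi, 2), cy, cx))
            th_ = g5.gather_nd((bi, ai, np.full_like(bi, 3), cy, cx))
            px = (tx_.sigmoid() * 2.0 - 0.5) * float(stride)
            py = (ty_.sigmoid() * 2.0 - 0.5) * float(stride)
            pw = (tw_.sigmoid() * 2.0).pow(2.0) * Tensor(aw)
            ph = (th_.sigmoid() * 2.0).pow(2.0) * Tensor(ah)
            ciou = _ciou(px, py, pw, ph,
                         Tensor(ox * stride), Tensor(oy * stride),
                         Tensor(tw), Tensor(th))
            box_terms.append((1.0 - ciou).sum())
            np.maximum.at(obj_t, (bi, ai, cy, cx),
                          np.clip(ciou.data, 0.0, 1.0).astype(np.float32))
        obj_logits = g5.gather_nd((slice(None),) * 2 + (4,))  # (n, NA, h, w)
        bce = bce_with_logits(obj_logits, obj_t).mean()
        scale_obj = bce * OBJ_BALANCE.get(stride, 1.0)
        obj_loss = scale_obj if obj_loss is None else obj_loss + scale_obj
    if box_terms:
        box_loss = box_terms[0]
        for t in box_terms[1:]:
            box_loss = box_loss + t
        box_loss = box_loss * (1.0 / n_pos_total)
    else:
        box_loss = Tensor(0.0)
    n_img = grids[0].shape[0]
    total = (box_loss * hp.box_gain + obj_loss * hp.obj_gain) * float(n_img)
    return box_loss, obj_loss, total


# ---------------------------------------------------------------------------
# matching and metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MatchResult:
    """Per-detection TP flags (confidence-descending) + missed-GT count."""

    tp_flags: tuple      # booleans, ordered by descending confidence
    confidences: tuple
    n_gt: int

    @property
    def tp(self) -> int:
        return sum(self.tp_flags)

    @property
    def fp(self) -> int:
        return len(self.tp_flags) - self.tp

    @property
    def fn(self) -> int:
        return self.n_gt - self.tp


@dataclass(frozen=True)
class MetricsReport:
    precision: float
    recall: float
    f1: float
    ap: dict            # class id -> AP
    map: float
    n_classes: int
    degenerate: bool = False  # a zero denominator was reported as 0


def match_detections(dets, gts, iou_threshold: float) -> MatchResult:
    """Greedy one-to-one matching for a single image and class.

    Detections are taken by descending confidence (stable for ties); a
    detection is TP iff its best-IoU *unmatched* ground truth reaches
    the threshold.
    """
    order = sorted(range(len(dets)), key=lambda i: (-dets[i].confidence, i))
    taken = [False] * len(gts)
    flags, confs = [], []
    for i in order:
        d = dets[i]
        best, best_iou = -1, 0.0
        for j, g in enumerate(gts):
            if taken[j]:
                continue
            v = box_iou(d.bbox, g)
            if v > best_iou:
                best_iou, best = v, j
        if best >= 0 and best_iou >= iou_threshold:
            taken[best] = True
            flags.append(True)
        else:
            flags.append(False)
        confs.append(d.confidence)
    return MatchResult(tuple(flags), tuple(confs), len(gts))


def pr_curve(flags, n_gt: int):
    """Cumulative precision/recall at every rank of a sorted flag stream."""
    flags = np.asarray(flags, dtype=bool)
    if n_gt == 0:
        if flags.size:
            raise ValueError("recall undefined: detections present but no ground truth")
        return np.array([]), np.array([])
    tp = np.cumsum(flags)
    fp = np.cumsum(~flags)
    precision = tp / (tp + fp)
    recall = tp / n_gt
    return precision, recall


def average_precision(precision, recall) -> float:
    """Area under the right-max precision envelope over recall in [0, 1]."""
    precision = np.asarray(precision, dtype=float)
    recall = np.asarray(recall, dtype=float)
    if precision.size == 0:
        import warnings

        warnings.warn("empty precision/recall curve; AP = 0")
        return 0.0
    mrec = np.concatenate(([0.0], recall, [1.0]))
    mpre = np.concatenate(([0.0], precision, [0.0]))
    mpre = np.maximum.accumulate(mpre[::-1])[::-1]
    return float(np.sum((mrec[1:] - mrec[:-1]) * mpre[1:]))


def metrics_report(matches, conf_threshold: float = 0.0) -> MetricsReport:
    """Aggregate per-image matches into P/R/F1/AP/mAP (single class).

    The precision/recall operating point counts detections at or above
    ``conf_threshold``; AP integrates the full ranking.
    """
    records = []
    n_gt = 0
    for m in matches:
        n_gt += m.n_gt
        records.extend(zip(m.confidences, m.tp_flags))
    records.sort(key=lambda r: -r[0])
    flags = [f for _, f in records]
    if n_gt == 0 and not flags:
        return MetricsReport(0.0, 0.0, 0.0, {0: 0.0}, 0.0, 1, degenerate=True)
    p_arr, r_arr = pr_curve(flags, n_gt)
    ap = average_precision(p_arr, r_arr)
    op = [(c, f) for c, f in records if c >= conf_threshold]
    tp = sum(1 for _, f in op if f)
    fp = len(op) - tp
    fn = n_gt - tp
    degenerate = (tp + fp == 0) or (tp + fn == 0)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return MetricsReport(precision, recall, f1, {0: ap}, ap, 1, degenerate)


def evaluate(model: Model, dataset: DetectionDataset, iou_threshold: float = 0.9,
             conf_threshold: float = 0.25, decode_threshold: float = 0.001,
             nms_iou: float = 0.45, batch_size: int = 8) -> MetricsReport:
    """Full evaluation pass: forward, decode, NMS, match, aggregate."""
    model.set_training(False)
    size = model.input_size
    matches = []
    for start in range(0, len(dataset), batch_size):
        imgs = dataset.images[start:start + batch_size]
        grids = model.forward(_to_batch(imgs, size))
        per_image = decode_predictions(grids, model.anchors, model.strides,
                                       decode_threshold, model.num_classes)
        for off, dets in enumerate(per_image):
            dets = nms(dets, nms_iou)
            gts = [decode_yolo_box(nb, size, size)
                   for nb in dataset.labels[start + off]]
            matches.append(match_detections(dets, gts, iou_threshold))
    model.set_training(True)
    return metrics_report(matches, conf_threshold)


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def _flip_sample(img: np.ndarray, boxes):
    flipped = img[:, ::-1].copy()
    return flipped, [NormalizedBox(b.class_id, 1.0 - b.cx, b.cy, b.w, b.h)
                     for b in boxes]


def train(model: Model, dataset: DetectionDataset, hp: Hyperparams,
          eval_every: int = 0, eval_iou: float = 0.5,
          checkpoint_dir=None, verbose: bool = False) -> list:
    """SGD training; returns one history record per epoch.

    ``dataset`` needs a ``train`` split (a ``val`` split enables
    best-checkpoint selection when ``eval_every`` > 0).  Fully
    deterministic for a fixed ``hp.seed``.
    """
    if "train" not in dataset.splits or not dataset.splits["train"]:
        raise ValueError("dataset has no training split")
    train_set = dataset.subset("train")
    val_set = dataset.subset("val") if dataset.splits.get("val") else None
    rng = np.random.default_rng(hp.seed)
    opt = SGD(model.parameters(), lr=hp.learning_rate, momentum=hp.momentum,
              weight_decay=hp.weight_decay)
    model.set_training(True)
    history = []
    best_map = -1.0
    size = model.input_size
    n = len(train_set)
    for epoch in range(hp.epochs):
        order = rng.permutation(n)
        ep_box = ep_obj = 0.0
        n_batches = 0
        for start in range(0, n, hp.batch_size):
            idx = order[start:start + hp.batch_size]
            imgs, targets = [], []
            for i in idx:
                img, boxes = train_set.images[i], train_set.labels[i]
                if rng.random() < hp.flip_prob:
                    img, boxes = _flip_sample(img, boxes)
                imgs.append(img)
                targets.append(boxes)
            grids = model.forward(_to_batch(imgs, size))
            box_l, obj_l, total = compute_loss(grids, targets, model, hp)
            opt.zero_grad()
            total.backward()
            opt.step()
            ep_box += float(box_l.data)
            ep_obj += float(obj_l.data)
            n_batches += 1
        rec = {"epoch": epoch, "box_loss": ep_box / n_batches,
               "obj_loss": ep_obj / n_batches}
        if eval_every and (epoch + 1) % eval_every == 0 and val_set is not None:
            rep = evaluate(model, val_set, iou_threshold=eval_iou)
            rec["val_map"] = rep.map
            if checkpoint_dir and rep.map > best_map:
                best_map = rep.map
                save_weights(model, Path(checkpoint_dir) / "best.npz")
        if verbose:
            print(f"epoch {epoch:4d}  box {rec['box_loss']:.4f}  obj {rec['obj_loss']:.4f}"
                  + (f"  val mAP {rec['val_map']:.3f}" if "val_map" in rec else ""))
        history.append(rec)
    if checkpoint_dir:
        save_weights(model, Path(checkpoint_dir) / "last.npz")
    return history


def save_weights(model: Model, path) -> None:
    sd = model.state_dict()
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **sd)


def load_weights(model: Model, path) -> None:
    with np.load(path) as f:
        model.load_state_dict({k: f[k] for k in f.files})
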