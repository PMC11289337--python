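"""Synthetic parasternal short-axis echocardiography fixtures.

Real echo frames of the aortic valve show a dark acoustic background,
an ultrasound sector (fan) of speckled tissue, and — in the short-axis
view — a bright ring (the valve annulus) whose three leaflets meet in a
Y during diastole and open into a central triangular orifice during
systole; calcific valves carry bright thickened patches on the
leaflets.  The generator reproduces those first-order features:

* multiplicative speckle: a Rayleigh-distributed field, lightly
  smoothed and multiplied onto the tissue intensity (zero tissue stays
  zero);
* one elliptical annulus per frame whose tight bounding box is the
  ground truth; box sides are drawn uniformly from ``box_side_range``
  (default 88-134 px at 768 px, the span of the fitted anchor priors),
  or around explicit ``box_modes`` when cluster-recovery experiments
  need multi-modal sizes;
* diastole/systole leaflet geometry and optional calcific blobs.

Everything is deterministic given (seed, index).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .annotations_io import BBox, encode_yolo_box, split_dataset, write_label_file

__all__ = ["SynthParams", "generate_image", "generate_dataset", "build_dataset"]


@dataclass(frozen=True)
class SynthParams:
    image_size: int = 768
    box_side_range: tuple = (88, 134)
    phase: str | None = None          # "diastole" | "systole" | None = random
    calcified: float = 0.5            # probability of calcific appearance
    speckle_scale: float = 0.5        # 0 = no speckle, 1 = full-variance speckle
    sector_angle: float = 75.0        # degrees
    seed: int = 0
    box_modes: tuple | None = None    # optional ((w, h), ...) size modes, +-3 px

    def __post_init__(self):
        lo, hi = self.box_side_range
        if not (0 < lo <= hi < self.image_size):
            raise ValueError(f"box_side_range {self.box_side_range} must fit the image")
        if not (0.0 <= self.calcified <= 1.0):
            raise ValueError("calcified must be a probability")
        if self.phase not in (None, "diastole", "systole"):
            raise ValueError(f"unknown phase {self.phase!r}")


def _rng_for(p: SynthParams, index: int) -> np.random.Generator:
    return np.random.default_rng([p.seed & 0x7FFFFFFF, index])


def _sector_mask(size: int, angle_deg: float):
    apex_y = -0.05 * size
    cy, cx = apex_y, size / 2
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    dy, dx = yy - cy, xx - cx
    r = np.hypot(dx, dy)
    theta = np.degrees(np.arctan2(dx, dy))  # 0 = straight down
    return (np.abs(theta) < angle_deg / 2) & (r < 1.12 * size) & (r > 0.08 * size)


def _sample_box(p: SynthParams, rng) -> tuple:
    if p.box_modes:
        w0, h0 = p.box_modes[rng.integers(len(p.box_modes))]
        w = w0 + rng.uniform(-3, 3)
        h = h0 + rng.uniform(-3, 3)
    else:
        lo, hi = p.box_side_range
        w = rng.uniform(lo, hi)
        h = rng.uniform(lo, hi)
    return w, h


def generate_image(p: SynthParams, index: int):
    """One synthetic frame: (uint8 image, ground-truth BBox, metadata)."""
    size = p.image_size
    rng = _rng_for(p, index)
    mask = _sector_mask(size, p.sector_angle)

    # smooth tissue intensity field (synthesised coarse, upsampled)
    coarse = size // 8
    base = rng.standard_normal((coarse, coarse))
    base = gaussian_filter(base, sigma=coarse / 12.0)
    base = np.kron(base, np.ones((8, 8)))
    base = gaussian_filter(base, sigma=4.0)
    base = (base - base.min()) / max(np.ptp(base), 1e-9)
    tissue = 35.0 + 55.0 * base

    # valve placement: rejection-sample a centre whose box stays in the sector
    w, h = _sample_box(p, rng)
    phase = p.phase or ("diastole" if rng.random() < 0.5 else "systole")
    for _ in range(100):
        cx = size * rng.uniform(0.35, 0.65)
        cy = size * rng.uniform(0.35, 0.65)
        x1, y1 = cx - w / 2, cy - h / 2
        x2, y2 = cx + w / 2, cy + h / 2
        xi = np.clip(np.round([x1, x2, x1, x2]).astype(int), 0, size - 1)
        yi = np.clip(np.round([y1, y1, y2, y2]).astype(int), 0, size - 1)
        if 0 <= x1 and 0 <= y1 and x2 < size and y2 < size and mask[yi, xi].all():
            break
    else:  # extremely defensive; the central region is always inside
        cx = cy = size / 2.0
        x1, y1, x2, y2 = cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2

    a, b = w / 2.0, h / 2.0
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    ex, ey = (xx - cx) / a, (yy - cy) / b
    d = np.hypot(ex, ey)
    ring_width = 0.16
    ring = (d <= 1.0) & (d >= 1.0 - ring_width)
    tissue[ring] += 150.0 + 30.0 * rng.random()

    phi0 = rng.uniform(0, 2 * np.pi)
    angles = phi0 + np.array([0.0, 2 * np.pi / 3, 4 * np.pi / 3])
    if phase == "diastole":
        # three leaflet chords meeting centrally (closed "Y" pattern)
        for ang in angles:
            t = np.linspace(0.0, 1.0 - ring_width / 2, 60)
            lx = cx + np.cos(ang) * a * t
            ly = cy + np.sin(ang) * b * t
            for px, py in zip(lx, ly):
                lo_x, hi_x = max(int(px) - 2, 0), min(int(px) + 3, size)
                lo_y, hi_y = max(int(py) - 2, 0), min(int(py) + 3, size)
                tissue[lo_y:hi_y, lo_x:hi_x] += 55.0
    else:
        # open central orifice: dark triangle with bright commissural edges
        vx = cx + np.cos(angles) * a * 0.55
        vy = cy + np.sin(angles) * b * 0.55
        det = ((vy[1] - vy[2]) * (vx[0] - vx[2]) + (vx[2] - vx[1]) * (vy[0] - vy[2]))
        l1 = ((vy[1] - vy[2]) * (xx - vx[2]) + (vx[2] - vx[1]) * (yy - vy[2])) / det
        l2 = ((vy[2] - vy[0]) * (xx - vx[2]) + (vx[0] - vx[2]) * (yy - vy[2])) / det
        l3 = 1.0 - l1 - l2
        tri = (l1 >= 0) & (l2 >= 0) & (l3 >= 0)
        tissue[tri] *= 0.25
        edge = tri & ~((l1 >= 0.08) & (l2 >= 0.08) & (l3 >= 0.08))
        tissue[edge] += 90.0

    calcific = bool(rng.random() < p.calcified)
    if calcific:
        for _ in range(int(rng.integers(1, 4))):
            ang = rng.uniform(0, 2 * np.pi)
            bx = cx + np.cos(ang) * a * (1.0 - ring_width / 2)
            by = cy + np.sin(ang) * b * (1.0 - ring_width / 2)
            rr = rng.uniform(4, 9)
            blob = np.exp(-(((xx - bx) ** 2 + (yy - by) ** 2) / (2 * rr * rr)))
            tissue += 120.0 * blob

    # multiplicative speckle (smoothed Rayleigh field, unit mean)
    s = np.clip(p.speckle_scale, 0.0, 1.0)
    if s > 0:
        ray = rng.rayleigh(scale=1.0, size=(size, size))
        ray = gaussian_filter(ray, sigma=1.2)
        ray /= ray.mean()
        field = (1.0 - s) + s * ray
        tissue = tissue * field

    img = np.where(mask, tissue, 6.0 * base)
    img = np.clip(img, 0, 255).astype(np.uint8)
    box = BBox(float(x1), float(y1), float(x2), float(y2))
    meta = {"phase": phase, "calcific": calcific, "index": index,
            "center": (float(cx), float(cy)), "size": (float(w), float(h))}
    return img, box, meta


def build_dataset(n: int, p: SynthParams, ratios=(0.80, 0.05, 0.15)):
    """In-memory dataset with train/val/test splits (no disk I/O)."""
    from .train_eval import DetectionDataset

    if n < 1:
        raise ValueError("n must be >= 1")
    images, labels, metas = [], [], []
    for i in range(n):
        img, box, meta = generate_image(p, i)
        images.append(img)
        labels.append([encode_yolo_box(box, p.image_size, p.image_size)])
        metas.append(meta)
    tr, va, te = split_dataset(list(range(n)), ratios, seed=p.seed)
    ds = DetectionDataset(images, labels,
                          {"train": tr, "val": va, "test": te})
    return ds, metas


def generate_dataset(n: int, p: SynthParams, out_dir, ratios=(0.80, 0.05, 0.15)) -> dict:
    """Write a YOLO-layout dataset (PNG images + label txt + data.yaml).

    Returns a manifest with per-split counts, the seed, and a content
    hash; also written to ``manifest.json`` in ``out_dir``.
    """
    from PIL import Image
    import yaml

    if n < 1:
        raise ValueError("n must be >= 1")
    out = Path(out_dir)
    splits = split_dataset(list(range(n)), ratios, seed=p.seed)
    split_of = {}
    for name, idxs in zip(("train", "val", "test"), splits):
        for i in idxs:
            split_of[i] = name
        (out / "images" / name).mkdir(parents=True, exist_ok=True)
        (out / "labels" / name).mkdir(parents=True, exist_ok=True)
    digest = hashlib.sha256()
    for i in range(n):
        img, box, _meta = generate_image(p, i)
        nb = encode_yolo_box(box, p.image_size, p.image_size)
        name = split_of[i]
        stem = f"img_{i:04d}"
        Image.fromarray(img).save(out / "images" / name / f"{stem}.png")
        write_label_file(out / "labels" / name / f"{stem}.txt", [nb])
        digest.update(img.tobytes())
        digest.update(f"{nb.cx:.6f}{nb.cy:.6f}{nb.w:.6f}{nb.h:.6f}".encode())
    data_yaml = {
        "path": ".",  # image/label dirs are relative to this file's directory
        "train": "images/train", "val": "images/val", "test": "images/test",
        "nc": 1, "names": ["aortic_valve"],
    }
    (out / "data.yaml").write_text(yaml.safe_dump(data_yaml, sort_keys=False))
    manifest = {
        "n": n,
        "seed": p.seed,
        "image_size": p.image_size,
        "counts": {nm: len(ix) for nm, ix in zip(("train", "val", "test"), splits)},
        "sha256": digest.hexdigest(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
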