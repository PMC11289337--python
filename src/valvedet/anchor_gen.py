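"""Dataset-specific anchor priors via K-means on ground-truth box sizes.

Lloyd's algorithm on raw (width, height) pixel pairs with Euclidean
distance, randomly initialised from the data.  The resulting k centres
are sorted by area and chunked into triples, smallest triple to the
highest-resolution (smallest-stride) active scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .arch_config import SCALE_STRIDES

__all__ = ["AnchorSet", "AnchorError", "kmeans_anchors", "assign_anchors"]


class AnchorError(ValueError):
    pass


@dataclass(frozen=True)
class AnchorSet:
    """k anchor (w, h) pairs plus their per-scale grouping."""

    anchors: tuple                # k (w, h) pairs, area-ascending
    per_scale: dict | None        # scale name -> 3 (w, h) pairs (None if k % 3)
    inertia: float                # final within-cluster sum of squares
    n_iter: int

    def __post_init__(self):
        if self.per_scale is not None and len(self.anchors) % 3 != 0:
            raise AnchorError("per-scale anchors require a multiple of 3")
        if any(w <= 0 or h <= 0 for w, h in self.anchors):
            raise AnchorError("anchor dims must be positive")


def _wcss(dims: np.ndarray, centers: np.ndarray, labels: np.ndarray) -> float:
    return float(((dims - centers[labels]) ** 2).sum())


def _lloyd(dims: np.ndarray, k: int, rng, tol: float, max_iter: int):
    n = dims.shape[0]
    centers = dims[rng.choice(n, size=k, replace=False)].copy()
    it = 0
    for it in range(1, max_iter + 1):
        d2 = ((dims[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        labels = d2.argmin(axis=1)
        new_centers = centers.copy()
        for j in range(k):
            members = dims[labels == j]
            if len(members):
                new_centers[j] = members.mean(axis=0)
            else:
                # re-seed an emptied cluster from the globally farthest point
                far = d2.min(axis=1).argmax()
                new_centers[j] = dims[far]
        move = np.abs(new_centers - centers).max()
        centers = new_centers
        if move < tol:
            break
    d2 = ((dims[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    labels = d2.argmin(axis=1)
    return centers, _wcss(dims, centers, labels), it


def kmeans_anchors(box_dims, k: int, seed: int = 0, tol: float = 1e-4,
                   max_iter: int = 300, n_init: int = 50,
                   active_scales=("P3", "P4", "P5")) -> AnchorSet:
    """Cluster (w, h) box dimensions into k anchor priors.

    ``box_dims`` are pixel pairs at the training input size (normalized
    labels must be de-normalized first).  Lloyd iteration stops when
    the largest centre movement drops below ``tol`` pixels; an emptied
    cluster is re-seeded from the point farthest from its centre.
    Initial centres are drawn randomly from the data; ``n_init``
    restarts are run and the lowest within-cluster sum of squares kept
    (plain random initialisation is prone to local optima).  Centres
    are rounded to integer pixels for reporting.
    """
    dims = np.asarray(box_dims, dtype=np.float64)
    if dims.ndim != 2 or dims.shape[1] != 2:
        raise AnchorError("box_dims must be an (n, 2) array of (w, h) pairs")
    if np.any(dims <= 0):
        raise AnchorError("box dimensions must be positive")
    n = dims.shape[0]
    if k < 1:
        raise AnchorError(f"k must be positive, got {k}")
    if n < k:
        raise AnchorError(f"need at least k={k} boxes, got {n}")
    if n_init < 1:
        raise AnchorError("n_init must be >= 1")

    rng = np.random.default_rng(seed)
    centers, inertia, it = None, np.inf, 0
    for _ in range(n_init):
        c, w_, i_ = _lloyd(dims, k, rng, tol, max_iter)
        if w_ < inertia:
            centers, inertia, it = c, w_, i_
    rounded = [(int(round(w)), int(round(h))) for w, h in centers]
    rounded.sort(key=lambda a: (a[0] * a[1], a[0]))
    if k % 3 == 0 and k >= 3 * len(set(active_scales)):
        per_scale = assign_anchors(rounded, active_scales)
        flat = tuple(a for triple in per_scale.values() for a in triple)
        return AnchorSet(anchors=flat, per_scale=per_scale, inertia=inertia, n_iter=it)
    return AnchorSet(anchors=tuple(rounded), per_scale=None, inertia=inertia, n_iter=it)


def assign_anchors(anchors, active_scales) -> dict:
    """Group anchors into triples per active scale, area-ascending.

    If more anchors are supplied than ``3 * |active_scales|`` (e.g. nine
    candidates for a two-scale model), the largest-area ones are kept —
    the pruned scales are the ones the small anchors belonged to.
    """
    scales = sorted(set(active_scales), key=SCALE_STRIDES.__getitem__)
    if not scales:
        raise AnchorError("no active scales")
    bad = [s for s in scales if s not in SCALE_STRIDES]
    if bad:
        raise AnchorError(f"unknown scales {bad}")
    anchors = sorted(((float(w), float(h)) for w, h in anchors),
                     key=lambda a: (a[0] * a[1], a[0]))
    need = 3 * len(scales)
    if len(anchors) < need or len(anchors) % 3 != 0:
        raise AnchorError(f"got {len(anchors)} anchors for {len(scales)} scales")
    anchors = anchors[len(anchors) - need:]
    out = {}
    for i, s in enumerate(scales):
        triple = anchors[3 * i:3 * (i + 1)]
        out[s] = tuple((int(w) if float(w).is_integer() else w,
                        int(h) if float(h).is_integer() else h) for w, h in triple)
    return out
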