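"""Building blocks of the detector: contracts, cost formulas and forward ops.

Two views of every block live here and are kept consistent by the test
suite:

* an *analytic* view — :func:`block_param_count`, :func:`block_flops`
  and :func:`block_output_shape` evaluate closed-form expressions on a
  :class:`BlockSpec`;
* a *runtime* view — small NumPy modules (:class:`ConvBNAct`,
  :class:`Focus`, :class:`CSP`, :class:`SPP`, ...) that hold weights
  and implement forward/backward through the autodiff engine.

Structural conventions (frozen; the published family statistics are the
reconciliation oracle):

* CBL = conv (no bias) -> batch norm -> activation (leaky-ReLU by
  default).
* DS-CBL = depth-wise conv -> BN -> point-wise 1x1 conv -> BN -> one
  trailing activation (MobileNet-style split of a spatial conv).
* CSP1_X / CSP2_X share the three-projection wrapper: two parallel 1x1
  CBL projections to half the output width, a stack of X units on one
  path, concat, then a 1x1 CBL fusion.  CSP1 units are residual
  bottlenecks (1x1 then 3x3 at full unit width, identity skip); CSP2
  units are the same 1x1/3x3 CBL pairs without the skip.
* In ``ds`` conv mode the spatial (3x3) convolutions inside CSP units
  are depth-wise separable; 1x1 projections are already point-wise.
* FLOPs are convolution multiply-accumulates at the output resolution;
  BN, activations and pooling are excluded.
* The layer count is the node count of the fused module tree: one node
  per block wrapper, per convolution *stage* (a DS pair is one stage),
  per activation; a pooling stage, upsample or concat counts once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat

__all__ = [
    "Shape", "BlockSpec", "BlockError",
    "block_output_shape", "block_param_count", "block_flops", "block_layer_count",
    "Module", "ConvBNAct", "Focus", "Bottleneck", "CSP", "SPP",
    "Upsample", "Concat", "DetectBranch", "make_block",
]

KINDS = ("focus", "cbl", "ds_cbl", "res", "csp1", "csp2", "spp",
         "upsample", "concat", "detect")


class BlockError(ValueError):
    """Invalid block specification or shape mismatch."""


@dataclass(frozen=True)
class Shape:
    channels: int
    height: int
    width: int

    def __post_init__(self):
        if min(self.channels, self.height, self.width) < 1:
            raise BlockError(f"Shape entries must be positive, got {self}")


@dataclass(frozen=True)
class BlockSpec:
    """One computational block and its channel/kernel/stride contract.

    ``repeats`` is the X of CSP1_X/CSP2_X.  For ``detect`` the spec
    describes a single scale branch; ``out_channels`` must equal
    ``na * (5 + nc)``.
    """

    kind: str
    in_channels: int
    out_channels: int
    kernel: int = 1
    stride: int = 1
    repeats: int = 1
    from_nodes: tuple = (-1,)

    def __post_init__(self):
        if self.kind not in KINDS:
            raise BlockError(f"unknown block kind {self.kind!r}")
        if self.in_channels < 1 or self.out_channels < 1:
            raise BlockError("channel counts must be positive")
        if self.kernel % 2 != 1 or self.kernel < 1:
            raise BlockError("kernel must be odd and positive")
        if self.stride not in (1, 2):
            raise BlockError("stride must be 1 or 2")
        if self.repeats < 1:
            raise BlockError("csp repeats must be >= 1")


# ---------------------------------------------------------------------------
# analytic view
# ---------------------------------------------------------------------------

def _conv_p(ci, co, k, bias=False):
    return ci * co * k * k + (co if bias else 0) + 2 * co  # weights + BN


def _ds_p(ci, co, k):
    return ci * k * k + 2 * ci + ci * co + 2 * co


def _csp_unit_p(c, ds):
    spatial = _ds_p(c, c, 3) if ds else _conv_p(c, c, 3)
    return _conv_p(c, c, 1) + spatial


def block_param_count(spec: BlockSpec) -> int:
    """Trainable parameters of the block (conv weights + 2 per BN channel).

    Equals a brute-force enumeration of the weight arrays of the
    corresponding runtime module.
    """
    ci, co, k, x = spec.in_channels, spec.out_channels, spec.kernel, spec.repeats
    if spec.kind == "cbl":
        return _conv_p(ci, co, k)
    if spec.kind == "ds_cbl":
        return _ds_p(ci, co, k)
    if spec.kind == "focus":
        return _conv_p(4 * ci, co, k)
    if spec.kind == "res":
        if ci != co:
            raise BlockError("res block requires in_channels == out_channels")
        return _csp_unit_p(co, ds=False)
    if spec.kind in ("csp1", "csp2"):
        c_ = co // 2
        if c_ < 1:
            raise BlockError("csp output width must be >= 2")
        wrapper = 2 * _conv_p(ci, c_, 1) + _conv_p(2 * c_, co, 1)
        return wrapper + x * _csp_unit_p(c_, ds=False)
    if spec.kind == "spp":
        c_ = ci // 2
        return _conv_p(ci, c_, 1) + _conv_p(4 * c_, co, 1)
    if spec.kind in ("upsample", "concat"):
        return 0
    if spec.kind == "detect":
        return (ci + 1) * co  # 1x1 conv with bias, no BN
    raise BlockError(spec.kind)


def csp_param_count(ci: int, co: int, repeats: int, ds: bool) -> int:
    """CSP1_X/CSP2_X parameters with optional depth-wise-separable units."""
    c_ = co // 2
    wrapper = 2 * _conv_p(ci, c_, 1) + _conv_p(2 * c_, co, 1)
    return wrapper + repeats * _csp_unit_p(c_, ds)


def block_output_shape(spec: BlockSpec, ins) -> Shape:
    """Output (channels, height, width) of a block.

    ``ins`` is one :class:`Shape`, or a list of shapes for ``concat``.
    """
    if spec.kind == "concat":
        shapes = list(ins)
        h, w = shapes[0].height, shapes[0].width
        if any(s.height != h or s.width != w for s in shapes):
            raise BlockError("concat inputs must agree spatially")
        total = sum(s.channels for s in shapes)
        if total != spec.in_channels:
            raise BlockError(f"concat channels {total} != spec {spec.in_channels}")
        return Shape(total, h, w)
    s: Shape = ins[0] if isinstance(ins, (list, tuple)) else ins
    if s.channels != spec.in_channels:
        raise BlockError(f"input channels {s.channels} != spec {spec.in_channels}")
    if spec.kind == "focus":
        if s.height % 2 or s.width % 2:
            raise BlockError("focus requires even spatial dims")
        return Shape(spec.out_channels, s.height // 2, s.width // 2)
    if spec.kind in ("cbl", "ds_cbl"):
        if spec.stride == 2 and (s.height % 2 or s.width % 2):
            raise BlockError("stride-2 block requires even spatial dims")
        return Shape(spec.out_channels, s.height // spec.stride, s.width // spec.stride)
    if spec.kind in ("res", "csp1", "csp2", "spp", "detect"):
        return Shape(spec.out_channels, s.height, s.width)
    if spec.kind == "upsample":
        return Shape(spec.out_channels, s.height * 2, s.width * 2)
    raise BlockError(spec.kind)


def _conv_f(h, w, ci, co, k):
    return h * w * k * k * ci * co


def _ds_f(h, w, ci, co, k):
    return h * w * ci * k * k + h * w * ci * co


def _csp_unit_f(h, w, c, ds):
    spatial = _ds_f(h, w, c, c, 3) if ds else _conv_f(h, w, c, c, 3)
    return _conv_f(h, w, c, c, 1) + spatial


def block_flops(spec: BlockSpec, ins) -> int:
    """Convolution multiply-accumulates of one forward pass of the block."""
    out = block_output_shape(spec, ins)
    h, w = out.height, out.width
    ci, co, k, x = spec.in_channels, spec.out_channels, spec.kernel, spec.repeats
    if spec.kind == "cbl":
        return _conv_f(h, w, ci, co, k)
    if spec.kind == "ds_cbl":
        return _ds_f(h, w, ci, co, k)
    if spec.kind == "focus":
        return _conv_f(h, w, 4 * ci, co, k)
    if spec.kind == "res":
        return _csp_unit_f(h, w, co, ds=False)
    if spec.kind in ("csp1", "csp2"):
        c_ = co // 2
        return (2 * _conv_f(h, w, ci, c_, 1) + _conv_f(h, w, 2 * c_, co, 1)
                + x * _csp_unit_f(h, w, c_, ds=False))
    if spec.kind == "spp":
        c_ = ci // 2
        return _conv_f(h, w, ci, c_, 1) + _conv_f(h, w, 4 * c_, co, 1)
    if spec.kind in ("upsample", "concat"):
        return 0
    if spec.kind == "detect":
        return _conv_f(h, w, ci, co, 1)
    raise BlockError(spec.kind)


def csp_flops(h, w, ci, co, repeats, ds) -> int:
    c_ = co // 2
    return (2 * _conv_f(h, w, ci, c_, 1) + _conv_f(h, w, 2 * c_, co, 1)
            + repeats * _csp_unit_f(h, w, c_, ds))


def block_layer_count(kind: str, repeats: int = 1) -> int:
    """Fused-module-tree node count of one block (see module docstring)."""
    if kind in ("cbl", "ds_cbl"):
        return 3
    if kind == "focus":
        return 4
    if kind == "res":
        return 7
    if kind in ("csp1", "csp2"):
        return 11 + 7 * repeats
    if kind == "spp":
        return 8
    if kind in ("upsample", "concat"):
        return 1
    if kind == "detect":
        return 1  # one conv per branch; the detect wrapper is counted by the model
    raise BlockError(kind)


# ---------------------------------------------------------------------------
# runtime view
# ---------------------------------------------------------------------------

class Module:
    """Tiny module base: named parameters, child traversal, train/eval."""

    def __init__(self):
        self._params: dict = {}
        self._children: dict = {}
        self.training = True

    def add_param(self, name: str, arr: np.ndarray) -> Tensor:
        t = Tensor(arr, requires_grad=True)
        self._params[name] = t
        return t

    def add_child(self, name: str, mod: "Module") -> "Module":
        self._children[name] = mod
        return mod

    def parameters(self):
        for t in self._params.values():
            yield t
        for c in self._children.values():
            yield from c.parameters()

    def named_parameters(self, prefix=""):
        for n, t in self._params.items():
            yield prefix + n, t
        for cn, c in self._children.items():
            yield from c.named_parameters(prefix + cn + ".")

    def param_count(self) -> int:
        return sum(int(np.prod(p.shape)) for p in self.parameters())

    def set_training(self, mode: bool):
        self.training = mode
        for c in self._children.values():
            c.set_training(mode)

    def state_dict(self) -> dict:
        out = {n: t.data.copy() for n, t in self.named_parameters()}
        for n, b in self.named_buffers():
            out[n] = b.copy()
        return out

    def load_state_dict(self, sd: dict):
        for n, t in self.named_parameters():
            t.data[...] = sd[n]
        for n, b in self.named_buffers():
            b[...] = sd[n]

    def named_buffers(self, prefix=""):
        for attr in ("running_mean", "running_var"):
            if attr in getattr(self, "_buffers", {}):
                yield prefix + attr, self._buffers[attr]
        for cn, c in self._children.items():
            yield from c.named_buffers(prefix + cn + ".")


class BatchNorm(Module):
    def __init__(self, c: int):
        super().__init__()
        self.gamma = self.add_param("gamma", np.ones(c, dtype=np.float32))
        self.beta = self.add_param("beta", np.zeros(c, dtype=np.float32))
        self._buffers = {"running_mean": np.zeros(c, dtype=np.float32),
                         "running_var": np.ones(c, dtype=np.float32)}

    def __call__(self, x: Tensor) -> Tensor:
        return x.batch_norm(self.gamma, self.beta,
                            self._buffers["running_mean"],
                            self._buffers["running_var"],
                            training=self.training)


def _act(x: Tensor, kind: str) -> Tensor:
    return x.silu() if kind == "silu" else x.leaky_relu(0.1)


def _he(rng, *shape):
    fan_in = int(np.prod(shape[1:]))
    return rng.normal(0.0, np.sqrt(2.0 / max(fan_in, 1)), size=shape).astype(np.float32)


class ConvBNAct(Module):
    """CBL (or DS-CBL) stage: convolution(s) + batch norm + activation."""

    def __init__(self, ci, co, k=1, s=1, rng=None, mode="standard",
                 act="leaky_relu", use_act=True):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.ci, self.co, self.k, self.s = ci, co, k, s
        self.mode, self.act_kind, self.use_act = mode, act, use_act
        if mode == "ds":
            self.dw = self.add_param("dw", _he(rng, ci, 1, k, k))
            self.bn1 = self.add_child("bn1", BatchNorm(ci))
            self.pw = self.add_param("pw", _he(rng, co, ci, 1, 1))
            self.bn2 = self.add_child("bn2", BatchNorm(co))
        else:
            self.w = self.add_param("w", _he(rng, co, ci, k, k))
            self.bn = self.add_child("bn", BatchNorm(co))

    def __call__(self, x: Tensor) -> Tensor:
        p = self.k // 2
        if self.mode == "ds":
            y = x.conv2d(self.dw, stride=self.s, padding=p, groups=self.ci)
            y = self.bn1(y)
            y = y.conv2d(self.pw)
            y = self.bn2(y)
        else:
            y = x.conv2d(self.w, stride=self.s, padding=p)
            y = self.bn(y)
        return _act(y, self.act_kind) if self.use_act else y


class Focus(Module):
    """Space-to-depth of four 2x2 slices followed by a CBL."""

    def __init__(self, ci, co, k=3, rng=None, act="leaky_relu"):
        super().__init__()
        self.conv = self.add_child("conv", ConvBNAct(4 * ci, co, k, 1, rng, act=act))

    def __call__(self, x: Tensor) -> Tensor:
        return self.conv(x.space_to_depth2())


class Bottleneck(Module):
    """1x1 then 3x3 CBL pair at full unit width, optional identity skip."""

    def __init__(self, c, rng=None, shortcut=True, mode="standard", act="leaky_relu"):
        super().__init__()
        self.shortcut = shortcut
        self.cv1 = self.add_child("cv1", ConvBNAct(c, c, 1, 1, rng, act=act))
        self.cv2 = self.add_child("cv2", ConvBNAct(c, c, 3, 1, rng, mode=mode, act=act))

    def __call__(self, x: Tensor) -> Tensor:
        y = self.cv2(self.cv1(x))
        return x + y if self.shortcut else y


class CSP(Module):
    """CSP1_X (residual units) / CSP2_X (plain units) split-merge block."""

    def __init__(self, ci, co, n, rng=None, shortcut=True, mode="standard",
                 act="leaky_relu"):
        super().__init__()
        c_ = co // 2
        self.cv1 = self.add_child("cv1", ConvBNAct(ci, c_, 1, 1, rng, act=act))
        self.cv2 = self.add_child("cv2", ConvBNAct(ci, c_, 1, 1, rng, act=act))
        self.units = [self.add_child(f"m{i}", Bottleneck(c_, rng, shortcut, mode, act))
                      for i in range(n)]
        self.cv3 = self.add_child("cv3", ConvBNAct(2 * c_, co, 1, 1, rng, act=act))

    def __call__(self, x: Tensor) -> Tensor:
        a = self.cv1(x)
        for u in self.units:
            a = u(a)
        return self.cv3(concat([a, self.cv2(x)], axis=1))


class SPP(Module):
    """Spatial pyramid pooling: parallel stride-1 max pools, concatenated."""

    def __init__(self, ci, co, pools=(5, 9, 13), rng=None, act="leaky_relu"):
        super().__init__()
        c_ = ci // 2
        self.pools = pools
        self.cv1 = self.add_child("cv1", ConvBNAct(ci, c_, 1, 1, rng, act=act))
        self.cv2 = self.add_child("cv2", ConvBNAct(c_ * (len(pools) + 1), co, 1, 1, rng, act=act))

    def __call__(self, x: Tensor) -> Tensor:
        y = self.cv1(x)
        return self.cv2(concat([y] + [y.maxpool_same(k) for k in self.pools], axis=1))


class Upsample(Module):
    def __call__(self, x: Tensor) -> Tensor:
        return x.upsample2x()


class Concat(Module):
    def __call__(self, xs) -> Tensor:
        return concat(list(xs), axis=1)


class DetectBranch(Module):
    """Per-scale 1x1 prediction conv with bias (the only biased conv)."""

    def __init__(self, ci, na, nc, rng=None, stride=None):
        super().__init__()
        self.na, self.nc = na, nc
        co = na * (5 + nc)
        self.w = self.add_param("w", (0.01 * rng.standard_normal((co, ci, 1, 1))).astype(np.float32)
                                if rng is not None else np.zeros((co, ci, 1, 1), np.float32))
        b = np.zeros(co, dtype=np.float32)
        if stride:
            # start objectness low so early training is not swamped by FPs
            b.reshape(na, 5 + nc)[:, 4] = -np.log(max((stride / 8.0) ** 2 * 64, 2.0))
        self.b = self.add_param("b", b)

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv2d(self.w, bias=self.b)


def make_block(spec: BlockSpec, rng=None, act="leaky_relu") -> Module:
    """Instantiate the runtime module matching an analytic ``BlockSpec``."""
    rng = rng or np.random.default_rng(0)
    ci, co, k, s, x = (spec.in_channels, spec.out_channels, spec.kernel,
                       spec.stride, spec.repeats)
    if spec.kind == "cbl":
        return ConvBNAct(ci, co, k, s, rng, act=act)
    if spec.kind == "ds_cbl":
        return ConvBNAct(ci, co, k, s, rng, mode="ds", act=act)
    if spec.kind == "focus":
        return Focus(ci, co, k, rng, act=act)
    if spec.kind == "res":
        return Bottleneck(co, rng, shortcut=True, act=act)
    if spec.kind == "csp1":
        return CSP(ci, co, x, rng, shortcut=True, act=act)
    if spec.kind == "csp2":
        return CSP(ci, co, x, rng, shortcut=False, act=act)
    if spec.kind == "spp":
        return SPP(ci, co, rng=rng, act=act)
    if spec.kind == "upsample":
        return Upsample()
    if spec.kind == "concat":
        return Concat()
    if spec.kind == "detect":
        nc = co // 3 - 5
        return DetectBranch(ci, 3, nc, rng)
    raise BlockError(spec.kind)
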