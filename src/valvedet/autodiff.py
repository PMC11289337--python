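"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The engine implements exactly the operator set the detector needs: 2-D
convolution (standard, grouped and depth-wise), batch normalisation,
leaky-ReLU/SiLU/sigmoid nonlinearities, stride-1 max pooling, nearest
2x upsampling, space-to-depth slicing, concatenation, elementwise
arithmetic (broadcasting), gathers and reductions.  Gradients are
accumulated through a topologically sorted backward pass, torch-style.

Arrays are float32 throughout; shapes follow the (N, C, H, W) layout.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "SGD", "concat", "stack_gather"]


def _sum_to_shape(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce a broadcast gradient back to ``shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents = ()

    # -- plumbing -------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- elementwise arithmetic ----------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))

    def _binary(self, other, fwd, bwd_self, bwd_other):
        other = Tensor._lift(other)
        out = Tensor(fwd(self.data, other.data))
        out.requires_grad = self.requires_grad or other.requires_grad
        if out.requires_grad:
            out._parents = (self, other)

            def _backward(g):
                if self.requires_grad:
                    self._accum(_sum_to_shape(bwd_self(g, self.data, other.data), self.shape))
                if other.requires_grad:
                    other._accum(_sum_to_shape(bwd_other(g, self.data, other.data), other.shape))

            out._backward = _backward
        return out

    def __add__(self, other):
        return self._binary(other, lambda a, b: a + b,
                            lambda g, a, b: g, lambda g, a, b: g)

    __radd__ = __add__

    def __sub__(self, other):
        return self._binary(other, lambda a, b: a - b,
                            lambda g, a, b: g, lambda g, a, b: -g)

    def __rsub__(self, other):
        return Tensor._lift(other).__sub__(self)

    def __mul__(self, other):
        return self._binary(other, lambda a, b: a * b,
                            lambda g, a, b: g * b, lambda g, a, b: g * a)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self._binary(other, lambda a, b: a / b,
                            lambda g, a, b: g / b, lambda g, a, b: -g * a / (b * b))

    def __rtruediv__(self, other):
        return Tensor._lift(other).__truediv__(self)

    def __neg__(self):
        return self * -1.0

    def _unary(self, fwd, bwd):
        out = Tensor(fwd(self.data))
        out.requires_grad = self.requires_grad
        if out.requires_grad:
            out._parents = (self,)
            out._backward = lambda g: self._accum(bwd(g, self.data, out.data))
        return out

    def pow(self, p: float):
        return self._unary(lambda a: a ** p, lambda g, a, o: g * p * a ** (p - 1))

    def sqrt(self):
        return self._unary(np.sqrt, lambda g, a, o: g * 0.5 / np.maximum(o, 1e-12))

    def exp(self):
        return self._unary(np.exp, lambda g, a, o: g * o)

    def log(self):
        return self._unary(np.log, lambda g, a, o: g / a)

    def atan(self):
        return self._unary(np.arctan, lambda g, a, o: g / (1.0 + a * a))

    def sigmoid(self):
        def fwd(a):
            out = np.empty_like(a)
            np.negative(np.abs(a), out=out)
            np.exp(out, out=out)
            pos = a >= 0
            out[pos] = 1.0 / (1.0 + out[pos])
            out[~pos] = out[~pos] / (1.0 + out[~pos])
            return out

        return self._unary(fwd, lambda g, a, o: g * o * (1.0 - o))

    def leaky_relu(self, slope: float = 0.1):
        return self._unary(lambda a: np.where(a > 0, a, slope * a),
                           lambda g, a, o: g * np.where(a > 0, 1.0, slope))

    def silu(self):
        def bwd(g, a, o):
            s = 1.0 / (1.0 + np.exp(-np.clip(a, -60, 60)))
            return g * (s + a * s * (1.0 - s))

        return self._unary(lambda a: a / (1.0 + np.exp(-np.clip(a, -60, 60))), bwd)

    def clamp(self, lo=None, hi=None):
        def bwd(g, a, o):
            m = np.ones_like(a)
            if lo is not None:
                m[a < lo] = 0.0
            if hi is not None:
                m[a > hi] = 0.0
            return g * m

        return self._unary(lambda a: np.clip(a, lo, hi), bwd)

    def maximum(self, other):
        return self._binary(other, np.maximum,
                            lambda g, a, b: g * (a >= b),
                            lambda g, a, b: g * (b > a))

    def minimum(self, other):
        return self._binary(other, np.minimum,
                            lambda g, a, b: g * (a <= b),
                            lambda g, a, b: g * (b < a))

    # -- reductions / shape --------------------------------------------

    def sum(self):
        out = Tensor(self.data.sum(keepdims=False))
        out.requires_grad = self.requires_grad
        if out.requires_grad:
            out._parents = (self,)
            out._backward = lambda g: self._accum(np.broadcast_to(g, self.shape))
        return out

    def mean(self):
        n = self.data.size
        return self.sum() * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(shape))
        out.requires_grad = self.requires_grad
        if out.requires_grad:
            out._parents = (self,)
            out._backward = lambda g: self._accum(g.reshape(self.shape))
        return out

    def transpose(self, axes):
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes))
        out.requires_grad = self.requires_grad
        if out.requires_grad:
            out._parents = (self,)
            out._backward = lambda g: self._accum(g.transpose(inv))
        return out

    def gather_nd(self, idx: tuple):
        """Fancy-index with fixed integer arrays; backward scatter-adds."""
        out = Tensor(self.data[idx])
        out.requires_grad = self.requires_grad
        if out.requires_grad:
            out._parents = (self,)

            def _backward(g):
                full = np.zeros(self.shape, dtype=np.float32)
                np.add.at(full, idx, g)
                self._accum(full)

            out._backward = _backward
        return out

    # -- neural-network primitives -------------------------------------

    def conv2d(self, weight: "Tensor", stride: int = 1, padding: int = 0,
               groups: int = 1, bias: "Tensor | None" = None) -> "Tensor":
        x, w = self.data, weight.data
        n, c, h, wd = x.shape
        co, cig, k, _ = w.shape
        if c != cig * groups:
            raise ValueError(f"channel mismatch: input {c}, weight expects {cig * groups}")
        xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding))) if padding else x
        hp, wp = xp.shape[2], xp.shape[3]
        ho, wo = (hp - k) // stride + 1, (wp - k) // stride + 1
        sN, sC, sH, sW = xp.strides
        patches = np.lib.stride_tricks.as_strided(
            xp, (n, c, ho, wo, k, k), (sN, sC, sH * stride, sW * stride, sH, sW))

        if groups == 1:
            cols = patches.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
            y = cols @ w.reshape(co, -1).T
            y = y.reshape(n, ho, wo, co).transpose(0, 3, 1, 2)
        elif groups == c and co == c and cig == 1:
            y = np.einsum("nchwij,cij->nchw", patches, w[:, 0], optimize=True)
        else:
            y = np.empty((n, co, ho, wo), dtype=np.float32)
            cg, cog = c // groups, co // groups
            for gi in range(groups):
                p = patches[:, gi * cg:(gi + 1) * cg]
                cols = p.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, cg * k * k)
                wg = w[gi * cog:(gi + 1) * cog].reshape(cog, -1)
                y[:, gi * cog:(gi + 1) * cog] = (cols @ wg.T).reshape(n, ho, wo, cog).transpose(0, 3, 1, 2)
        y = np.ascontiguousarray(y, dtype=np.float32)
        if bias is not None:
            y += bias.data.reshape(1, -1, 1, 1)

        out = Tensor(y)
        out.requires_grad = self.requires_grad or weight.requires_grad or (
            bias is not None and bias.requires_grad)
        if not out.requires_grad:
            return out
        out._parents = tuple(t for t in (self, weight, bias) if t is not None)

        def _backward(g):
            if bias is not None and bias.requires_grad:
                bias._accum(g.sum(axis=(0, 2, 3)))
            need_x = self.requires_grad
            cg, cog = c // groups, co // groups
            dxp = np.zeros_like(xp) if need_x else None
            dw = np.zeros_like(w) if weight.requires_grad else None
            for gi in range(groups):
                gy = g[:, gi * cog:(gi + 1) * cog]  # (n, cog, ho, wo)
                gyc = gy.transpose(0, 2, 3, 1).reshape(n * ho * wo, cog)
                p = patches[:, gi * cg:(gi + 1) * cg]
                if dw is not None:
                    cols = p.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, cg * k * k)
                    dw[gi * cog:(gi + 1) * cog] = (gyc.T @ cols).reshape(cog, cg, k, k)
                if need_x:
                    wg = w[gi * cog:(gi + 1) * cog].reshape(cog, -1)
                    dcols = (gyc @ wg).reshape(n, ho, wo, cg, k, k)
                    # col2im: accumulate each kernel offset
                    for ki in range(k):
                        for kj in range(k):
                            dxp[:, gi * cg:(gi + 1) * cg,
                                ki:ki + ho * stride:stride,
                                kj:kj + wo * stride:stride] += dcols[:, :, :, :, ki, kj].transpose(0, 3, 1, 2)
            if dw is not None:
                weight._accum(dw)
            if need_x:
                dx = dxp[:, :, padding:hp - padding, padding:wp - padding] if padding else dxp
                self._accum(dx)

        out._backward = _backward
        return out

    def batch_norm(self, gamma: "Tensor", beta: "Tensor",
                   running_mean: np.ndarray | None = None,
                   running_var: np.ndarray | None = None,
                   training: bool = True, momentum: float = 0.1,
                   eps: float = 1e-5) -> "Tensor":
        x = self.data
        if training:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            if running_mean is not None:
                running_mean *= 1.0 - momentum
                running_mean += momentum * mu
                m = x.shape[0] * x.shape[2] * x.shape[3]
                running_var *= 1.0 - momentum
                running_var += momentum * var * (m / max(m - 1, 1))
        else:
            mu, var = running_mean, running_var
        inv = 1.0 / np.sqrt(var + eps)
        xhat = (x - mu.reshape(1, -1, 1, 1)) * inv.reshape(1, -1, 1, 1)
        y = gamma.data.reshape(1, -1, 1, 1) * xhat + beta.data.reshape(1, -1, 1, 1)

        out = Tensor(y)
        out.requires_grad = self.requires_grad or gamma.requires_grad or beta.requires_grad
        if not out.requires_grad:
            return out
        out._parents = (self, gamma, beta)

        def _backward(g):
            if beta.requires_grad:
                beta._accum(g.sum(axis=(0, 2, 3)))
            if gamma.requires_grad:
                gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
            if self.requires_grad:
                gk = g * gamma.data.reshape(1, -1, 1, 1)
                if training:
                    m = x.shape[0] * x.shape[2] * x.shape[3]
                    s1 = gk.sum(axis=(0, 2, 3), keepdims=True)
                    s2 = (gk * xhat).sum(axis=(0, 2, 3), keepdims=True)
                    dx = (gk - s1 / m - xhat * s2 / m) * inv.reshape(1, -1, 1, 1)
                else:
                    dx = gk * inv.reshape(1, -1, 1, 1)
                self._accum(dx.astype(np.float32))

        out._backward = _backward
        return out

    def maxpool_same(self, k: int) -> "Tensor":
        """Stride-1 max pool with odd kernel and same-size padded output."""
        pad = k // 2
        xp = np.pad(self.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)),
                    constant_values=-np.inf)
        n, c, hp, wp = xp.shape
        h, w = self.shape[2], self.shape[3]
        sN, sC, sH, sW = xp.strides
        win = np.lib.stride_tricks.as_strided(xp, (n, c, h, w, k, k),
                                              (sN, sC, sH, sW, sH, sW))
        y = win.max(axis=(4, 5))
        out = Tensor(y)
        out.requires_grad = self.requires_grad
        if out.requires_grad:
            out._parents = (self,)

            def _backward(g):
                dxp = np.zeros_like(xp)
                assigned = np.zeros_like(y, dtype=bool)
                for ki in range(k):
                    for kj in range(k):
                        sl = xp[:, :, ki:ki + h, kj:kj + w]
                        m = (sl == y) & ~assigned
                        assigned |= m
                        dxp[:, :, ki:ki + h, kj:kj + w] += g * m
                self._accum(dxp[:, :, pad:pad + h, pad:pad + w])

            out._backward = _backward
        return out

    def upsample2x(self) -> "Tensor":
        out = Tensor(self.data.repeat(2, axis=2).repeat(2, axis=3))
        out.requires_grad = self.requires_grad
        if out.requires_grad:
            out._parents = (self,)
            n, c, h, w = self.shape
            out._backward = lambda g: self._accum(
                g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))
        return out

    def space_to_depth2(self) -> "Tensor":
        """Four 2x2-strided slices stacked on channels (the Focus slicing)."""
        x = self.data
        parts = [x[:, :, ::2, ::2], x[:, :, 1::2, ::2],
                 x[:, :, ::2, 1::2], x[:, :, 1::2, 1::2]]
        out = Tensor(np.concatenate(parts, axis=1))
        out.requires_grad = self.requires_grad
        if out.requires_grad:
            out._parents = (self,)
            c = self.shape[1]

            def _backward(g):
                dx = np.zeros_like(x)
                dx[:, :, ::2, ::2] = g[:, 0 * c:1 * c]
                dx[:, :, 1::2, ::2] = g[:, 1 * c:2 * c]
                dx[:, :, ::2, 1::2] = g[:, 2 * c:3 * c]
                dx[:, :, 1::2, 1::2] = g[:, 3 * c:4 * c]
                self._accum(dx)

            out._backward = _backward
        return out


def concat(tensors: list, axis: int = 1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis))
    out.requires_grad = any(t.requires_grad for t in tensors)
    if out.requires_grad:
        out._parents = tuple(tensors)
        sizes = [t.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def _backward(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                if t.requires_grad:
                    t._accum(piece)

        out._backward = _backward
    return out


def stack_gather(t: Tensor, idx: tuple) -> Tensor:
    return t.gather_nd(idx)


class SGD:
    """Stochastic gradient descent with momentum and decoupled-style weight decay."""

    def __init__(self, params, lr: float, momentum: float = 0.0,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._vel = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        for p, v in zip(self.params, self._vel):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay and p.data.ndim > 1:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v
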