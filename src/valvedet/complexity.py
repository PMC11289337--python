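"""Analytic convolution cost model and whole-model profiling.

For an output feature map of size H x W, kernel K, Cin input channels
and Nconv filters:

    cost_conv   = H * W * K * K * Cin * Nconv
    cost_dsconv = H * W * Cin * K * K  +  H * W * Cin * Nconv

so the depth-wise-separable/standard ratio is exactly
``1/Nconv + 1/K**2`` independent of H, W and Cin.

GFLOPs reported by :func:`profile_model` are convolution
multiply-accumulates x 2 (multiply + add), at a 640-px input by
default; batch norm, activations and pooling are excluded.  Timed
inference is informational only — it depends on the host.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from fractions import Fraction

from .model_graph import Model

__all__ = ["ComplexityReport", "cost_conv", "cost_dsconv", "cost_ratio",
           "profile_model"]

DEFAULT_PROFILE_SIZE = 640


@dataclass(frozen=True)
class ComplexityReport:
    name: str
    layers: int
    parameters: int
    gflops: float
    input_size: int
    inference_ms: float | None = None  # hardware-dependent; None unless timed


def _check_positive(**kw):
    for name, v in kw.items():
        if not isinstance(v, (int,)) or v < 1:
            raise ValueError(f"{name} must be a positive integer, got {v!r}")


def cost_conv(H: int, W: int, K: int, Cin: int, Nconv: int) -> int:
    """Multiply-accumulates of a standard convolution."""
    _check_positive(H=H, W=W, K=K, Cin=Cin, Nconv=Nconv)
    return H * W * K * K * Cin * Nconv


def cost_dsconv(H: int, W: int, K: int, Cin: int, Nconv: int) -> int:
    """Multiply-accumulates of a depth-wise + point-wise convolution pair."""
    _check_positive(H=H, W=W, K=K, Cin=Cin, Nconv=Nconv)
    return H * W * Cin * K * K + H * W * Cin * Nconv


def cost_ratio(K: int, Nconv: int, exact: bool = False):
    """Separable/standard cost ratio ``1/Nconv + 1/K**2``."""
    _check_positive(K=K, Nconv=Nconv)
    r = Fraction(1, Nconv) + Fraction(1, K * K)
    return r if exact else float(r)


def profile_model(model: Model, input_size: int | None = None,
                  timed: bool = False, n_runs: int = 50) -> ComplexityReport:
    """Layers/parameters/GFLOPs (and optionally median latency) of a model."""
    if not isinstance(model, Model):
        raise TypeError("profile_model expects a built Model")
    size = input_size or DEFAULT_PROFILE_SIZE
    gflops = 2.0 * model.flop_count(size) / 1e9
    ms = None
    if timed:
        import numpy as np

        model.set_training(False)
        x = np.zeros((1, 3, size, size), dtype=np.float32)
        model.forward(x)  # warm-up
        times = []
        for _ in range(max(n_runs, 1)):
            t0 = time.perf_counter()
            model.forward(x)
            times.append(1e3 * (time.perf_counter() - t0))
        ms = float(np.median(times))
        model.set_training(True)
    return ComplexityReport(
        name=model.config.name,
        layers=model.layer_count(),
        parameters=model.parameter_count(),
        gflops=gflops,
        input_size=size,
        inference_ms=ms,
    )
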