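"""Analytic parameter and FLOPs accounting.

All arithmetic is exact integer (or :class:`~fractions.Fraction`) — no
floating-point drift.  Conventions:

* A standard convolution with kernel ``H_K × H_K``, ``C`` input channels,
  ``C'`` output channels on an ``H_F × H_F`` feature map costs
  ``H_K² · C · C' · H_F²`` multiply operations; the depthwise-separable
  factorization costs ``H_K² · C · H_F² + C · C' · H_F²``, a ratio of
  ``1/C' + 1/H_K²`` (≈ ×9 cheaper for 3×3 kernels at wide outputs).
* Forward-pass FLOPs of a convolutional layer: ``H² · (C·K + 1) · C'`` with
  ``K`` the kernel AREA (k²) and ``H`` the layer's OUTPUT spatial size; of a
  dense layer: ``(2I − 1) · O``.
* Batch-norm, activation, pooling, add and multiply layers are assigned zero
  FLOPs — the accounting covers convolutional and dense compute only, which
  dominates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import pandas as pd

from .graph import ModelGraph


@dataclass(frozen=True)
class ConvCostSpec:
    """Shape of one convolution for cost comparison."""

    kernel_size: int
    in_channels: int
    out_channels: int
    feature_size: int

    def __post_init__(self) -> None:
        for v in (self.kernel_size, self.in_channels, self.out_channels, self.feature_size):
            if v < 1:
                raise ValueError("all ConvCostSpec fields must be >= 1")


def conv_cost(spec: ConvCostSpec) -> int:
    """Multiply count of a standard convolution: H_K²·C·C'·H_F²."""
    return spec.kernel_size**2 * spec.in_channels * spec.out_channels * spec.feature_size**2


def separable_cost(spec: ConvCostSpec) -> int:
    """Multiply count of the depthwise + pointwise factorization."""
    hf2 = spec.feature_size**2
    return spec.kernel_size**2 * spec.in_channels * hf2 + spec.in_channels * spec.out_channels * hf2


def cost_ratio(spec: ConvCostSpec) -> Fraction:
    """Exact separable/standard cost ratio; equals 1/C' + 1/H_K²."""
    return Fraction(separable_cost(spec), conv_cost(spec))


def reduction_factor(kernel_size: int, out_channels: int = 10**6) -> Fraction:
    """Fold-reduction of the separable factorization (reciprocal ratio)."""
    spec = ConvCostSpec(kernel_size, 1, out_channels, 1)
    return 1 / cost_ratio(spec)


def layer_flops(h: int, c: int, k_area: int, c_out: int) -> int:
    """Convolutional-layer FLOPs: H²·(C·K + 1)·C' with K the kernel area."""
    if min(h, c, k_area, c_out) < 1:
        raise ValueError("all arguments must be >= 1")
    return h**2 * (c * k_area + 1) * c_out


def dense_flops(i: int, o: int) -> int:
    """Dense-layer FLOPs: (2I − 1)·O."""
    if i < 1 or o < 1:
        raise ValueError("I and O must be >= 1")
    return (2 * i - 1) * o


@dataclass
class FlopsReport:
    """Per-layer and aggregate cost of a model graph."""

    graph_name: str
    input_size: int
    rows: list[dict] = field(default_factory=list)  # name, kind, params, flops
    conv_flops: int = 0
    dense_flops: int = 0
    n_params: int = 0

    @property
    def total_flops(self) -> int:
        return self.conv_flops + self.dense_flops

    @property
    def gflops(self) -> float:
        return self.total_flops / 1e9

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.rows, columns=["layer", "kind", "params", "flops"])
        total = pd.DataFrame(
            [{"layer": "TOTAL", "kind": "", "params": self.n_params,
              "flops": self.total_flops}]
        )
        return pd.concat([df, total], ignore_index=True)

    def __str__(self) -> str:
        lines = [f"model: {self.graph_name}  (input {self.input_size}×{self.input_size}×3)"]
        lines.append(self.to_frame().to_string(index=False))
        lines.append(
            f"conv FLOPs: {self.conv_flops:,}  dense FLOPs: {self.dense_flops:,}  "
            f"total: {self.total_flops:,} ({self.gflops:.4f} GFLOPs), "
            f"params: {self.n_params:,}"
        )
        return "\n".join(lines)


def profile(graph: ModelGraph, input_size: int | None = None) -> FlopsReport:
    """Account parameters and forward FLOPs for every layer of a graph.

    ``input_size`` overrides the graph's declared input resolution.  Spatial
    sizes are propagated through the graph, and each convolutional layer is
    charged at its post-convolution size; layers the conventions exclude
    (BN, activations, pooling, add, multiply) appear with zero FLOPs.
    """
    if input_size is not None and input_size != graph.input_size:
        graph = ModelGraph.from_dict({**graph.to_dict(), "input_size": input_size})
    shapes = graph.shapes()
    report = FlopsReport(graph.name, graph.input_size)
    for spec in graph.layers:
        h_out, _ = shapes[spec.name]
        flops = 0
        if spec.kind == "conv":
            flops = layer_flops(max(h_out, 1), spec.in_channels,
                                spec.kernel_size**2, spec.out_channels)
        elif spec.kind == "dwconv":
            # one single-channel kernel per output channel
            flops = layer_flops(max(h_out, 1), spec.depth_multiplier,
                                spec.kernel_size**2, spec.out_channels)
        elif spec.kind == "pwconv":
            flops = layer_flops(max(h_out, 1), spec.in_channels, 1, spec.out_channels)
        elif spec.kind == "dense":
            flops = dense_flops(spec.in_channels, spec.out_channels)
        if spec.kind == "dense":
            report.dense_flops += flops
        else:
            report.conv_flops += flops
        report.n_params += spec.n_params
        report.rows.append(
            {"layer": spec.name, "kind": spec.kind, "params": spec.n_params,
             "flops": flops}
        )
    return report
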