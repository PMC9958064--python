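"""Network builders: compressed EfficientNet backbone, fusion, residual block.

The model family is built around a truncated EfficientNetB0: only the stem
and the entry inverted-bottleneck (MBConv) stage survive, bringing the
backbone from ~5 M parameters down to under 20 K (the "compressed
EfficientNet", CEN).  Two independently initialized CEN branches process the
same image and their feature maps are fused by elementwise addition (FCEN),
recovering feature diversity lost to truncation without lengthening the
network.  A modified residual skip block (MRSB) — a 1×1 depthwise
convolution, SeLU, and a pointwise convolution around an identity skip —
regularizes the fused features, and a GAP → dense → softmax head closes the
classifier.

All builders return :class:`~cenkd.graph.ModelGraph` objects (or layer
fragments); instantiation into trainable weights happens in
:mod:`cenkd.engine`.
"""

from __future__ import annotations

import numpy as np

from .graph import LayerSpec, ModelGraph

#: hard budget on trainable parameters of the truncated backbone
CEN_PARAM_BUDGET = 20_000

#: EfficientNetB0 stem width and entry-stage width
STEM_CHANNELS = 32
ENTRY_CHANNELS = 16

#: squeeze-and-excitation reduction ratio (EfficientNet convention)
SE_REDUCTION = 4

MBCONV_VARIANTS = ("MBConv-A", "MBConv-B")
BLOCK_VARIANTS = MBCONV_VARIANTS + ("SEBlock", "MRSB")


def fuse(features_a: np.ndarray, features_b: np.ndarray) -> np.ndarray:
    """Elementwise feature fusion: x_fused = F1 ⊕ F2 (addition)."""
    a = np.asarray(features_a)
    b = np.asarray(features_b)
    if a.shape != b.shape:
        raise ValueError(f"fuse requires identical shapes, got {a.shape} vs {b.shape}")
    return a + b


def build_se_block(channels: int, reduction_ratio: int = SE_REDUCTION,
                   prefix: str = "se", input_name: str = "in") -> list[LayerSpec]:
    """Squeeze-and-excitation gate: GAP → PWConv(swish) → PWConv(sigmoid) → ⊗.

    The fragment's first layer consumes ``input_name``; the final multiply
    gates that same tensor.
    """
    squeeze = channels // reduction_ratio
    if squeeze < 1:
        raise ValueError(
            f"reduction ratio {reduction_ratio} squeezes {channels} channels below 1"
        )
    return [
        LayerSpec(f"{prefix}_gap", "gap", [input_name],
                  in_channels=channels, out_channels=channels),
        LayerSpec(f"{prefix}_reduce", "pwconv", [f"{prefix}_gap"],
                  in_channels=channels, out_channels=squeeze),
        LayerSpec(f"{prefix}_reduce_act", "activation", [f"{prefix}_reduce"],
                  in_channels=squeeze, out_channels=squeeze, activation="swish"),
        LayerSpec(f"{prefix}_expand", "pwconv", [f"{prefix}_reduce_act"],
                  in_channels=squeeze, out_channels=channels),
        LayerSpec(f"{prefix}_gate", "activation", [f"{prefix}_expand"],
                  in_channels=channels, out_channels=channels, activation="sigmoid"),
        LayerSpec(f"{prefix}_scale", "multiply", [input_name, f"{prefix}_gate"],
                  in_channels=channels, out_channels=channels),
    ]


def build_mbconv(variant: str, in_channels: int, out_channels: int,
                 stride: int | None = None, prefix: str = "mb",
                 input_name: str = "in") -> list[LayerSpec]:
    """Entry inverted-bottleneck block.

    Layer order: k×k conv → BN → swish → 3×3/1 depthwise conv → BN → swish →
    SE gate ⊗ → swish.  Variant A leads with a 3×3/2 convolution; variant B
    is its stride-1 twin.  Convolutions followed by BN carry no bias.
    """
    if variant not in MBCONV_VARIANTS:
        raise ValueError(f"unknown MBConv variant {variant!r}")
    if stride is None:
        stride = 2 if variant == "MBConv-A" else 1
    layers = [
        LayerSpec(f"{prefix}_conv", "conv", [input_name], kernel_size=3, stride=stride,
                  in_channels=in_channels, out_channels=out_channels, use_bias=False),
        LayerSpec(f"{prefix}_bn1", "batchnorm", [f"{prefix}_conv"],
                  in_channels=out_channels, out_channels=out_channels),
        LayerSpec(f"{prefix}_swish1", "activation", [f"{prefix}_bn1"],
                  in_channels=out_channels, out_channels=out_channels, activation="swish"),
        LayerSpec(f"{prefix}_dwconv", "dwconv", [f"{prefix}_swish1"], kernel_size=3,
                  stride=1, in_channels=out_channels, out_channels=out_channels,
                  use_bias=False),
        LayerSpec(f"{prefix}_bn2", "batchnorm", [f"{prefix}_dwconv"],
                  in_channels=out_channels, out_channels=out_channels),
        LayerSpec(f"{prefix}_swish2", "activation", [f"{prefix}_bn2"],
                  in_channels=out_channels, out_channels=out_channels, activation="swish"),
    ]
    layers += build_se_block(out_channels, SE_REDUCTION, prefix=f"{prefix}_se",
                             input_name=f"{prefix}_swish2")
    layers.append(
        LayerSpec(f"{prefix}_out", "activation", [f"{prefix}_se_scale"],
                  in_channels=out_channels, out_channels=out_channels,
                  activation="swish")
    )
    return layers


def _stem(prefix: str, input_name: str, in_channels: int = 3) -> list[LayerSpec]:
    return [
        LayerSpec(f"{prefix}_conv", "conv", [input_name], kernel_size=3, stride=2,
                  in_channels=in_channels, out_channels=STEM_CHANNELS, use_bias=False),
        LayerSpec(f"{prefix}_bn", "batchnorm", [f"{prefix}_conv"],
                  in_channels=STEM_CHANNELS, out_channels=STEM_CHANNELS),
        LayerSpec(f"{prefix}_swish", "activation", [f"{prefix}_bn"],
                  in_channels=STEM_CHANNELS, out_channels=STEM_CHANNELS,
                  activation="swish"),
    ]


def cen_fragment(prefix: str, input_name: str, in_channels: int = 3,
                 budget: int = CEN_PARAM_BUDGET) -> list[LayerSpec]:
    """Stem plus entry MBConv stage, truncated greedily under the budget.

    Whole blocks are appended in order — the stride-2 entry block first, then
    stride-1 twins — for as long as the running trainable-parameter total
    stays within ``budget``.
    """
    layers = _stem(prefix, input_name, in_channels)
    total = sum(s.n_params for s in layers)
    if total > budget:
        raise ValueError("stem alone exceeds the parameter budget")
    tail = f"{prefix}_swish"
    block_idx = 0
    while True:
        variant = "MBConv-A" if block_idx == 0 else "MBConv-B"
        cin = STEM_CHANNELS if block_idx == 0 else ENTRY_CHANNELS
        candidate = build_mbconv(variant, cin, ENTRY_CHANNELS,
                                 prefix=f"{prefix}_b{block_idx}", input_name=tail)
        cost = sum(s.n_params for s in candidate)
        if total + cost > budget:
            break
        layers += candidate
        total += cost
        tail = f"{prefix}_b{block_idx}_out"
        block_idx += 1
    return layers


def build_cen(input_size: int = 224, seed: int = 0,
              budget: int = CEN_PARAM_BUDGET) -> ModelGraph:
    """The compressed EfficientNet backbone as a standalone graph."""
    if input_size < 32:
        raise ValueError("input_size must be >= 32")
    layers = [LayerSpec("image", "input", in_channels=3, out_channels=3)]
    layers += cen_fragment("cen", "image", budget=budget)
    return ModelGraph("cen", input_size=input_size, input_channels=3,
                      seed=seed, layers=layers)


def build_mrsb(channels: int, prefix: str = "mrsb",
               input_name: str = "in") -> list[LayerSpec]:
    """Modified residual skip block.

    Main branch: 1×1 depthwise conv (depth 1) → SeLU → 1×1 pointwise conv;
    skip: identity, merged by addition with no activation afterwards
    (pre-activation style).  No k>1 convolution appears anywhere in the block.
    """
    if channels < 1:
        raise ValueError("channels must be >= 1")
    return [
        LayerSpec(f"{prefix}_dwconv", "dwconv", [input_name], kernel_size=1, stride=1,
                  in_channels=channels, out_channels=channels),
        LayerSpec(f"{prefix}_selu", "activation", [f"{prefix}_dwconv"],
                  in_channels=channels, out_channels=channels, activation="selu"),
        LayerSpec(f"{prefix}_pwconv", "pwconv", [f"{prefix}_selu"],
                  in_channels=channels, out_channels=channels),
        LayerSpec(f"{prefix}_add", "add", [f"{prefix}_pwconv", input_name],
                  in_channels=channels, out_channels=channels),
    ]


def attach_head(backbone: ModelGraph, num_classes: int) -> ModelGraph:
    """Append GAP → dense(num_classes) → softmax; logits stay addressable."""
    if num_classes < 2:
        raise ValueError("num_classes must be >= 2")
    h, c = backbone.shapes()[backbone.output.name]
    if h < 1:
        raise ValueError("head requires a spatial feature map")
    tail = backbone.output.name
    backbone.extend([
        LayerSpec("head_gap", "gap", [tail], in_channels=c, out_channels=c),
        LayerSpec("head_dense", "dense", ["head_gap"],
                  in_channels=c, out_channels=num_classes),
        LayerSpec("head_softmax", "activation", ["head_dense"],
                  in_channels=num_classes, out_channels=num_classes,
                  activation="softmax"),
    ])
    return backbone


def build_student(input_size: int = 224, num_classes: int = 6,
                  seed: int = 0) -> ModelGraph:
    """The full fused student: two CEN branches → ⊕ → MRSB → head.

    The branches share architecture but not weights — each is initialized
    from its own stream, so the mirror branch contributes a stochastically
    different feature set from the same input.
    """
    if input_size < 32:
        raise ValueError("input_size must be >= 32")
    layers = [LayerSpec("image", "input", in_channels=3, out_channels=3)]
    layers += cen_fragment("cen1", "image")
    layers += cen_fragment("cen2", "image")
    names = [s.name for s in layers]
    tail1 = [n for n in names if n.startswith("cen1")][-1]
    tail2 = [n for n in names if n.startswith("cen2")][-1]
    c = ENTRY_CHANNELS
    layers.append(LayerSpec("fused", "add", [tail1, tail2],
                            in_channels=c, out_channels=c))
    layers += build_mrsb(c, prefix="mrsb", input_name="fused")
    graph = ModelGraph("student", input_size=input_size, input_channels=3,
                       seed=seed, layers=layers)
    return attach_head(graph, num_classes)


def build_teacher(input_size: int = 64, num_classes: int = 6,
                  seed: int = 0, width: int = 24) -> ModelGraph:
    """A small reference CNN used as the distillation teacher at desk scale.

    Two stride-2 conv/BN/ReLU stages and a linear head — enough capacity to
    outperform the compressed student on the synthetic task while staying
    cheap to train without accelerators.
    """
    if num_classes < 2:
        raise ValueError("num_classes must be >= 2")
    w1, w2 = width, 2 * width
    layers = [
        LayerSpec("image", "input", in_channels=3, out_channels=3),
        LayerSpec("c1", "conv", ["image"], kernel_size=3, stride=2,
                  in_channels=3, out_channels=w1, use_bias=False),
        LayerSpec("bn1", "batchnorm", ["c1"], in_channels=w1, out_channels=w1),
        LayerSpec("act1", "activation", ["bn1"], in_channels=w1,
                  out_channels=w1, activation="relu"),
        LayerSpec("c2", "conv", ["act1"], kernel_size=3, stride=2,
                  in_channels=w1, out_channels=w2, use_bias=False),
        LayerSpec("bn2", "batchnorm", ["c2"], in_channels=w2, out_channels=w2),
        LayerSpec("act2", "activation", ["bn2"], in_channels=w2,
                  out_channels=w2, activation="relu"),
    ]
    graph = ModelGraph("teacher", input_size=input_size, input_channels=3,
                       seed=seed, layers=layers)
    return attach_head(graph, num_classes)
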