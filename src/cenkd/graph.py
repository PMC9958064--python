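"""Framework-independent model graphs.

A :class:`ModelGraph` is an ordered, acyclic list of :class:`LayerSpec` nodes
with explicit edges (each node names its input nodes).  The same description
drives three consumers: instantiation into a trainable numpy model
(:mod:`cenkd.engine`), analytic parameter counting, and FLOPs accounting
(:mod:`cenkd.cost`).  Graphs serialize to a plain YAML document so the CLI
``profile`` subcommand can consume a graph written by any other tool.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import yaml

#: closed set of layer kinds a graph may contain
LAYER_KINDS = frozenset(
    {
        "input",
        "conv",
        "dwconv",
        "pwconv",
        "batchnorm",
        "activation",
        "gap",
        "dense",
        "add",
        "multiply",
    }
)

ACTIVATIONS = frozenset({"selu", "swish", "relu", "sigmoid", "softmax", "none"})


@dataclass
class LayerSpec:
    """One node of a model graph.

    ``inputs`` lists the names of parent nodes; convolutional kinds use
    ``kernel_size``/``stride``, ``dwconv`` additionally ``depth_multiplier``
    (the per-channel depth Ψ, default 1, so out_channels = in_channels · Ψ).
    ``use_bias`` is False for convolutions immediately followed by batch
    normalization, True elsewhere.
    """

    name: str
    kind: str
    inputs: list[str] = field(default_factory=list)
    kernel_size: int = 1
    stride: int = 1
    in_channels: int = 1
    out_channels: int = 1
    activation: str = "none"
    depth_multiplier: int = 1
    use_bias: bool = True

    def __post_init__(self) -> None:
        if self.kind not in LAYER_KINDS:
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.kernel_size < 1 or self.stride < 1:
            raise ValueError("kernel_size and stride must be >= 1")
        if self.in_channels < 1 or self.out_channels < 1:
            raise ValueError("channel counts must be >= 1")
        if self.kind == "dwconv" and self.out_channels != self.in_channels * self.depth_multiplier:
            raise ValueError("dwconv requires out_channels = in_channels * depth_multiplier")

    @property
    def n_params(self) -> int:
        """Trainable parameter count of this layer alone."""
        k2 = self.kernel_size**2
        if self.kind == "conv":
            n = k2 * self.in_channels * self.out_channels
            return n + (self.out_channels if self.use_bias else 0)
        if self.kind == "dwconv":
            n = k2 * self.in_channels * self.depth_multiplier
            return n + (self.out_channels if self.use_bias else 0)
        if self.kind == "pwconv":
            n = self.in_channels * self.out_channels
            return n + (self.out_channels if self.use_bias else 0)
        if self.kind == "batchnorm":
            return 2 * self.out_channels  # gamma, beta
        if self.kind == "dense":
            return self.in_channels * self.out_channels + (self.out_channels if self.use_bias else 0)
        return 0


@dataclass
class ModelGraph:
    """Ordered DAG of layers with a single input and a single output node."""

    name: str
    input_size: int
    input_channels: int = 3
    layers: list[LayerSpec] = field(default_factory=list)
    #: default weight-initialization seed used when the graph is instantiated
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # -- structure ---------------------------------------------------------

    def validate(self) -> None:
        seen: set[str] = set()
        n_inputs = 0
        for spec in self.layers:
            if spec.name in seen:
                raise ValueError(f"duplicate layer name {spec.name!r}")
            if spec.kind == "input":
                n_inputs += 1
                if spec.inputs:
                    raise ValueError("input node cannot have parents")
            else:
                for parent in spec.inputs:
                    if parent not in seen:
                        raise ValueError(
                            f"layer {spec.name!r} references {parent!r} before definition"
                        )
                if not spec.inputs:
                    raise ValueError(f"layer {spec.name!r} has no inputs")
            seen.add(spec.name)
        if n_inputs != 1:
            raise ValueError("graph must have exactly one input node")
        consumed = {p for s in self.layers for p in s.inputs}
        sinks = [s for s in self.layers if s.name not in consumed]
        if len(sinks) != 1:
            raise ValueError(f"graph must have exactly one output node, found {len(sinks)}")

    @property
    def output(self) -> LayerSpec:
        consumed = {p for s in self.layers for p in s.inputs}
        return next(s for s in self.layers if s.name not in consumed)

    def __getitem__(self, name: str) -> LayerSpec:
        for spec in self.layers:
            if spec.name == name:
                return spec
        raise KeyError(name)

    # -- shapes ------------------------------------------------------------

    def shapes(self) -> dict[str, tuple[int, int]]:
        """Propagate the input through every layer.

        Returns ``{layer name: (spatial size, channels)}``; fully connected
        outputs have spatial size 0.  Raises ``ValueError`` on any shape
        inconsistency, including a stride that exhausts the spatial extent.
        """
        out: dict[str, tuple[int, int]] = {}
        for spec in self.layers:
            if spec.kind == "input":
                out[spec.name] = (self.input_size, self.input_channels)
                continue
            parents = [out[p] for p in spec.inputs]
            h, c = parents[0]
            if spec.kind in ("conv", "dwconv", "pwconv"):
                if c != spec.in_channels:
                    raise ValueError(
                        f"{spec.name}: expects {spec.in_channels} channels, got {c}"
                    )
                if h > 0:
                    h_out = math.ceil(h / spec.stride)  # 'same' padding
                    if h_out < 1:
                        raise ValueError(f"{spec.name}: spatial extent exhausted")
                else:
                    h_out = 0
                out[spec.name] = (h_out, spec.out_channels)
            elif spec.kind in ("batchnorm", "activation"):
                out[spec.name] = (h, c)
            elif spec.kind == "gap":
                out[spec.name] = (0, c)
            elif spec.kind == "dense":
                if c != spec.in_channels:
                    raise ValueError(
                        f"{spec.name}: expects {spec.in_channels} inputs, got {c}"
                    )
                out[spec.name] = (0, spec.out_channels)
            elif spec.kind == "add":
                for ph, pc in parents[1:]:
                    if (ph, pc) != (h, c):
                        raise ValueError(f"{spec.name}: add requires equal shapes")
                out[spec.name] = (h, c)
            elif spec.kind == "multiply":
                # broadcast gate: (H, C) x (0 or 1, C)
                gh, gc = parents[1]
                if gc != c:
                    raise ValueError(f"{spec.name}: gate channel mismatch")
                out[spec.name] = (h, c)
            else:  # pragma: no cover
                raise AssertionError(spec.kind)
        return out

    @property
    def n_params(self) -> int:
        return sum(spec.n_params for spec in self.layers)

    # -- composition -------------------------------------------------------

    def extend(self, fragment: list[LayerSpec]) -> None:
        """Append a fragment whose first layer already references this graph."""
        self.layers.extend(fragment)
        self.validate()

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "input_size": self.input_size,
            "input_channels": self.input_channels,
            "seed": self.seed,
            "layers": [asdict(spec) for spec in self.layers],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "ModelGraph":
        layers = [LayerSpec(**entry) for entry in payload["layers"]]
        return cls(
            name=payload["name"],
            input_size=payload["input_size"],
            input_channels=payload.get("input_channels", 3),
            seed=payload.get("seed", 0),
            layers=layers,
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ModelGraph":
        return cls.from_dict(yaml.safe_load(text))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_yaml())

    @classmethod
    def load(cls, path) -> "ModelGraph":
        with open(path) as fh:
            return cls.from_yaml(fh.read())
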