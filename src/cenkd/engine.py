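"""Lightweight numpy runtime for model graphs.

Instantiates a :class:`~cenkd.graph.ModelGraph` into a trainable model with
explicit forward and backward passes and an Adam optimizer.  The runtime is
deliberately small: it supports exactly the layer kinds a graph may declare
(standard, depthwise and pointwise convolutions, batch normalization,
elementwise activations, global average pooling, dense, add, multiply) on
NHWC float64 tensors, which is all the compressed-network family here needs.

Weight initialization is LeCun-normal (std = 1/sqrt(fan_in)), the variance-
preserving choice that the self-normalizing SeLU activation assumes.  Every
layer draws from its own seeded generator derived from the model seed and
the layer name, so two structurally identical branches with different layer
names start from different weights while the whole model stays
bit-reproducible for a given seed.
"""

from __future__ import annotations

import math
import zlib

import numpy as np

from .activations import FORWARD, GRAD
from .graph import ModelGraph

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.9


def _layer_rng(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng([seed, zlib.crc32(name.encode())])


def _same_pad(h: int, k: int, s: int) -> tuple[int, int, int]:
    """'same' padding: output ceil(h/s); returns (h_out, pad_before, pad_after)."""
    h_out = math.ceil(h / s)
    pad_total = max((h_out - 1) * s + k - h, 0)
    before = pad_total // 2
    return h_out, before, pad_total - before


def _im2col(x: np.ndarray, k: int, s: int) -> tuple[np.ndarray, tuple]:
    """Extract k x k patches -> (N, Ho, Wo, k, k, C); also return scatter info."""
    n, h, w, c = x.shape
    ho, pb, pa = _same_pad(h, k, s)
    wo = ho  # square inputs throughout
    xp = np.pad(x, ((0, 0), (pb, pa), (pb, pa), (0, 0)))
    cols = np.empty((n, ho, wo, k, k, c), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, :, i, j, :] = xp[:, i : i + ho * s : s, j : j + wo * s : s, :]
    return cols, (x.shape, xp.shape, pb, s, k, ho)


def _col2im(dcols: np.ndarray, info: tuple) -> np.ndarray:
    x_shape, xp_shape, pb, s, k, ho = info
    dxp = np.zeros(xp_shape, dtype=dcols.dtype)
    for i in range(k):
        for j in range(k):
            dxp[:, i : i + ho * s : s, j : j + ho * s : s, :] += dcols[:, :, :, i, j, :]
    n, h, w, c = x_shape
    return dxp[:, pb : pb + h, pb : pb + w, :]


class Model:
    """A model graph instantiated with concrete weights."""

    def __init__(self, graph: ModelGraph, seed: int | None = None,
                 dtype=np.float32):
        graph.shapes()  # raises on inconsistency
        self.graph = graph
        self.seed = graph.seed if seed is None else seed
        self.dtype = np.dtype(dtype)
        self.params: dict[str, dict[str, np.ndarray]] = {}
        self.state: dict[str, dict[str, np.ndarray]] = {}  # batch-norm running stats
        self._cache: dict | None = None
        self._init_weights()
        # node whose output are the classifier logits: parent of a final
        # softmax activation, else the output node itself
        out = graph.output
        if out.kind == "activation" and out.activation == "softmax":
            self.logits_node = out.inputs[0]
        else:
            self.logits_node = out.name

    # -- initialization ----------------------------------------------------

    def _init_weights(self) -> None:
        for spec in self.graph.layers:
            rng = _layer_rng(self.seed, spec.name)
            if spec.kind == "conv":
                fan_in = spec.kernel_size**2 * spec.in_channels
                w = rng.normal(0.0, 1.0 / math.sqrt(fan_in),
                               (spec.kernel_size, spec.kernel_size,
                                spec.in_channels, spec.out_channels))
                p = {"W": w}
                if spec.use_bias:
                    p["b"] = np.zeros(spec.out_channels)
                self.params[spec.name] = p
            elif spec.kind == "dwconv":
                if spec.depth_multiplier != 1:
                    raise NotImplementedError("runtime supports depth multiplier 1")
                fan_in = spec.kernel_size**2
                w = rng.normal(0.0, 1.0 / math.sqrt(fan_in),
                               (spec.kernel_size, spec.kernel_size, spec.in_channels))
                p = {"W": w}
                if spec.use_bias:
                    p["b"] = np.zeros(spec.out_channels)
                self.params[spec.name] = p
            elif spec.kind == "pwconv":
                w = rng.normal(0.0, 1.0 / math.sqrt(spec.in_channels),
                               (spec.in_channels, spec.out_channels))
                p = {"W": w}
                if spec.use_bias:
                    p["b"] = np.zeros(spec.out_channels)
                self.params[spec.name] = p
            elif spec.kind == "batchnorm":
                self.params[spec.name] = {
                    "gamma": np.ones(spec.out_channels),
                    "beta": np.zeros(spec.out_channels),
                }
                self.state[spec.name] = {
                    "mean": np.zeros(spec.out_channels),
                    "var": np.ones(spec.out_channels),
                }
            elif spec.kind == "dense":
                w = rng.normal(0.0, 1.0 / math.sqrt(spec.in_channels),
                               (spec.in_channels, spec.out_channels))
                p = {"W": w}
                if spec.use_bias:
                    p["b"] = np.zeros(spec.out_channels)
                self.params[spec.name] = p
        # weights are drawn in float64 for seed-stable values, then held in
        # the runtime dtype
        for p in self.params.values():
            for key in p:
                p[key] = p[key].astype(self.dtype)
        for st in self.state.values():
            for key in st:
                st[key] = st[key].astype(self.dtype)

    @property
    def n_params(self) -> int:
        return sum(int(a.size) for p in self.params.values() for a in p.values())

    # -- forward -----------------------------------------------------------

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Run the graph; returns the output node's value.

        ``x`` is NHWC (or NHW for grayscale upcast by the caller).  Caches
        intermediates for :meth:`backward` when ``training`` is True.
        """
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim != 4:
            raise ValueError("expected NHWC input")
        acts: dict[str, np.ndarray] = {}
        aux: dict[str, tuple] = {}
        for spec in self.graph.layers:
            name, kind = spec.name, spec.kind
            if kind == "input":
                acts[name] = x
                continue
            a = acts[spec.inputs[0]]
            p = self.params.get(name, {})
            if kind == "conv":
                k = spec.kernel_size
                cols, info = _im2col(a, k, spec.stride)
                n, ho, wo = cols.shape[:3]
                flat = cols.reshape(n, ho, wo, -1)
                out = flat @ p["W"].reshape(-1, spec.out_channels)
                if spec.use_bias:
                    out = out + p["b"]
                acts[name] = out
                aux[name] = (flat, info)
            elif kind == "dwconv":
                cols, info = _im2col(a, spec.kernel_size, spec.stride)
                out = np.einsum("nhwijc,ijc->nhwc", cols, p["W"])
                if spec.use_bias:
                    out = out + p["b"]
                acts[name] = out
                aux[name] = (cols, info)
            elif kind == "pwconv":
                out = a @ p["W"]
                if spec.use_bias:
                    out = out + p["b"]
                acts[name] = out
                aux[name] = (a,)
            elif kind == "batchnorm":
                if training:
                    mu = a.mean(axis=(0, 1, 2))
                    var = a.var(axis=(0, 1, 2))
                    st = self.state[name]
                    st["mean"] = _BN_MOMENTUM * st["mean"] + (1 - _BN_MOMENTUM) * mu
                    st["var"] = _BN_MOMENTUM * st["var"] + (1 - _BN_MOMENTUM) * var
                else:
                    st = self.state[name]
                    mu, var = st["mean"], st["var"]
                inv = 1.0 / np.sqrt(var + _BN_EPS)
                xhat = (a - mu) * inv
                acts[name] = p["gamma"] * xhat + p["beta"]
                aux[name] = (xhat, inv)
            elif kind == "activation":
                if spec.activation == "softmax":
                    z = a.reshape(a.shape[0], -1)
                    z = z - z.max(axis=1, keepdims=True)
                    e = np.exp(z)
                    acts[name] = e / e.sum(axis=1, keepdims=True)
                elif spec.activation == "none":
                    acts[name] = a
                else:
                    acts[name] = np.asarray(FORWARD[spec.activation](a))
                    aux[name] = (a,)
            elif kind == "gap":
                acts[name] = a.mean(axis=(1, 2), keepdims=True)
                aux[name] = (a.shape,)
            elif kind == "dense":
                flat = a.reshape(a.shape[0], -1)
                out = flat @ p["W"]
                if spec.use_bias:
                    out = out + p["b"]
                acts[name] = out
                aux[name] = (flat, a.shape)
            elif kind == "add":
                out = acts[spec.inputs[0]].copy()
                for parent in spec.inputs[1:]:
                    out += acts[parent]
                acts[name] = out
            elif kind == "multiply":
                acts[name] = acts[spec.inputs[0]] * acts[spec.inputs[1]]
        self._cache = {"acts": acts, "aux": aux, "training": training}
        return acts[self.graph.output.name]

    def logits(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Forward pass returning the pre-softmax class scores (N, classes)."""
        self.forward(x, training=training)
        return self._cache["acts"][self.logits_node]  # type: ignore[index]

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Class probabilities on the standard (τ=1) softmax, batched."""
        outs = []
        for start in range(0, len(x), batch_size):
            outs.append(self.forward(x[start : start + batch_size], training=False))
        out = np.concatenate(outs, axis=0)
        return out.reshape(len(x), -1)

    def predict(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        return self.predict_proba(x, batch_size=batch_size).argmax(axis=1)

    # -- backward ----------------------------------------------------------

    def backward(self, grad_logits: np.ndarray) -> dict[str, dict[str, np.ndarray]]:
        """Backpropagate a gradient at the logits node; returns param grads.

        Requires a preceding ``forward(..., training=True)``.  Batch-norm
        gradients use the batch statistics of that pass.
        """
        if self._cache is None or not self._cache["training"]:
            raise RuntimeError("backward requires forward(training=True) first")
        acts, aux = self._cache["acts"], self._cache["aux"]
        grads: dict[str, np.ndarray] = {
            self.logits_node: np.asarray(grad_logits, dtype=self.dtype)
        }
        pgrads: dict[str, dict[str, np.ndarray]] = {}
        # walk layers in reverse; skip anything downstream of the logits node
        active = False
        for spec in reversed(self.graph.layers):
            if spec.name == self.logits_node:
                active = True
            if not active or spec.name not in grads:
                continue
            d = grads.pop(spec.name)
            name, kind = spec.name, spec.kind
            p = self.params.get(name, {})

            def send(parent: str, g: np.ndarray) -> None:
                if parent in grads:
                    grads[parent] = grads[parent] + g
                else:
                    grads[parent] = g

            if kind == "input":
                continue
            if kind == "conv":
                flat, info = aux[name]
                n, ho, wo, kk = flat.shape
                dout = d.reshape(-1, spec.out_channels)
                dw = flat.reshape(-1, kk).T @ dout
                pg = {"W": dw.reshape(p["W"].shape)}
                if spec.use_bias:
                    pg["b"] = dout.sum(axis=0)
                pgrads[name] = pg
                dflat = d @ p["W"].reshape(-1, spec.out_channels).T
                k = spec.kernel_size
                dcols = dflat.reshape(n, ho, wo, k, k, spec.in_channels)
                send(spec.inputs[0], _col2im(dcols, info))
            elif kind == "dwconv":
                cols, info = aux[name]
                pg = {"W": np.einsum("nhwijc,nhwc->ijc", cols, d)}
                if spec.use_bias:
                    pg["b"] = d.sum(axis=(0, 1, 2))
                pgrads[name] = pg
                dcols = np.einsum("nhwc,ijc->nhwijc", d, p["W"])
                send(spec.inputs[0], _col2im(dcols, info))
            elif kind == "pwconv":
                (a,) = aux[name]
                pg = {"W": np.tensordot(a, d, axes=([0, 1, 2], [0, 1, 2]))}
                if spec.use_bias:
                    pg["b"] = d.sum(axis=(0, 1, 2))
                pgrads[name] = pg
                send(spec.inputs[0], d @ p["W"].T)
            elif kind == "batchnorm":
                xhat, inv = aux[name]
                m = float(np.prod(xhat.shape[:3]))
                dgamma = (d * xhat).sum(axis=(0, 1, 2))
                dbeta = d.sum(axis=(0, 1, 2))
                pgrads[name] = {"gamma": dgamma, "beta": dbeta}
                dx = (p["gamma"] * inv / m) * (m * d - dbeta - xhat * dgamma)
                send(spec.inputs[0], dx)
            elif kind == "activation":
                if spec.activation in ("none", "softmax"):
                    send(spec.inputs[0], d)
                else:
                    (a,) = aux[name]
                    send(spec.inputs[0], d * np.asarray(GRAD[spec.activation](a)))
            elif kind == "gap":
                (in_shape,) = aux[name]
                h, w = in_shape[1], in_shape[2]
                send(spec.inputs[0], np.broadcast_to(d / (h * w), in_shape).copy())
            elif kind == "dense":
                flat, in_shape = aux[name]
                pg = {"W": flat.T @ d}
                if spec.use_bias:
                    pg["b"] = d.sum(axis=0)
                pgrads[name] = pg
                send(spec.inputs[0], (d @ p["W"].T).reshape(in_shape))
            elif kind == "add":
                for parent in spec.inputs:
                    send(parent, d)
            elif kind == "multiply":
                main, gate = spec.inputs
                send(main, d * acts[gate])
                dg = d * acts[main]
                # reduce over broadcast axes of the gate
                while dg.ndim > acts[gate].ndim:
                    dg = dg.sum(axis=1)
                for ax in range(dg.ndim):
                    if acts[gate].shape[ax] == 1 and dg.shape[ax] != 1:
                        dg = dg.sum(axis=ax, keepdims=True)
                send(gate, dg)
        return pgrads

    # -- persistence -------------------------------------------------------

    def save(self, prefix: str) -> None:
        """Write ``<prefix>.yaml`` (graph) and ``<prefix>.npz`` (weights)."""
        self.graph.save(f"{prefix}.yaml")
        flat = {}
        for lname, p in self.params.items():
            for pname, arr in p.items():
                flat[f"{lname}/{pname}"] = arr
        for lname, st in self.state.items():
            for sname, arr in st.items():
                flat[f"{lname}//{sname}"] = arr
        np.savez(f"{prefix}.npz", **flat)

    @classmethod
    def load(cls, prefix: str) -> "Model":
        graph = ModelGraph.load(f"{prefix}.yaml")
        model = cls(graph)
        with np.load(f"{prefix}.npz") as data:
            for key in data.files:
                if "//" in key:
                    lname, sname = key.split("//")
                    model.state[lname][sname] = data[key]
                else:
                    lname, pname = key.split("/")
                    model.params[lname][pname] = data[key]
        return model


class Adam:
    """Adam optimizer over a model's parameter dict."""

    def __init__(self, model: Model, learning_rate: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.model = model
        self.lr = learning_rate
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: {n: np.zeros_like(a) for n, a in p.items()}
                  for k, p in model.params.items()}
        self.v = {k: {n: np.zeros_like(a) for n, a in p.items()}
                  for k, p in model.params.items()}

    def step(self, grads: dict[str, dict[str, np.ndarray]]) -> None:
        self.t += 1
        bc1 = 1 - self.b1**self.t
        bc2 = 1 - self.b2**self.t
        for lname, pg in grads.items():
            for pname, g in pg.items():
                m = self.m[lname][pname]
                v = self.v[lname][pname]
                m *= self.b1
                m += (1 - self.b1) * g
                v *= self.b2
                v += (1 - self.b2) * g * g
                self.model.params[lname][pname] -= (
                    self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
                )
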