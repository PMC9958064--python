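"""Knowledge-distillation objective and training protocols.

A large teacher's class scores, softened through a temperature-scaled
softmax ``Q(τ) = exp(L/τ) / Σ exp(L/τ)``, supervise a compact student next
to the ground-truth labels.  The objective mixes a "soft" term — the KL
divergence between the teacher's and student's tempered distributions — with
the usual "hard" categorical cross-entropy at τ=1:

    Total = Soft · (1 − α) + Hard · α

τ defaults to 2 and α to 0.3.  The soft loss carries no τ² rescaling and the
temperature is applied to both teacher and student logits, so at τ=1 the
soft term is the plain KL between the two softmax outputs.  Two training
entry points are provided: :func:`train_classifier` (standard supervised
training, Adam, lr 1e-4, 30 epochs, batch 16) and :func:`distill` (teacher
frozen, lr 1e-3, same schedule).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import DatasetManifest, load_arrays
from .engine import Adam, Model
from .graph import ModelGraph

_EPS = 1e-12

#: learning rates: distillation stage vs ordinary (teacher / non-KD) training
KD_LEARNING_RATE = 1e-3
BASE_LEARNING_RATE = 1e-4


@dataclass
class KDConfig:
    """Distillation and training hyper-parameters."""

    temperature: float = 2.0
    alpha: float = 0.3
    learning_rate: float | None = None  # None -> protocol default
    batch_size: int = 16
    epochs: int = 30
    optimizer: str = "adam"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must lie in [0, 1]")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")


def tempered_softmax(logits, tau: float = 1.0) -> np.ndarray:
    """Temperature-scaled softmax along the last axis, max-shift stabilized.

    τ=1 recovers the standard softmax; τ>1 softens the distribution.
    """
    if tau <= 0:
        raise ValueError("temperature must be > 0")
    z = np.asarray(logits, dtype=float) / tau
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def soft_loss(teacher_probs, student_probs) -> float:
    """KL(teacher ‖ student) summed over classes (mean over a batch), nats."""
    t = np.asarray(teacher_probs, dtype=float)
    s = np.asarray(student_probs, dtype=float)
    if t.shape != s.shape:
        raise ValueError("probability vectors must have matching shapes")
    s = np.clip(s, _EPS, None)
    t_safe = np.clip(t, _EPS, None)
    kl = np.sum(t * (np.log(t_safe) - np.log(s)), axis=-1)
    return float(np.mean(kl))


def hard_loss(predictions, labels) -> float:
    """Categorical cross-entropy −ln p[true class], mean over a batch, nats."""
    p = np.atleast_2d(np.asarray(predictions, dtype=float))
    y = np.atleast_1d(np.asarray(labels))
    if np.any(y < 0) or np.any(y >= p.shape[-1]):
        raise IndexError("label index out of range")
    picked = np.clip(p[np.arange(len(y)), y], _EPS, None)
    return float(np.mean(-np.log(picked)))


def total_loss(soft: float, hard: float, alpha: float) -> float:
    """Weighted objective: soft·(1 − α) + hard·α."""
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must lie in [0, 1]")
    return soft * (1 - alpha) + hard * alpha


# -- training loops --------------------------------------------------------


def _one_hot(y: np.ndarray, n: int) -> np.ndarray:
    out = np.zeros((len(y), n))
    out[np.arange(len(y)), y] = 1.0
    return out


def _check_data(manifest: DatasetManifest, graph: ModelGraph) -> None:
    counts = manifest.class_counts("train")
    if any(c == 0 for c in counts):
        empty = [manifest.classes[i] for i, c in enumerate(counts) if c == 0]
        raise ValueError(f"empty training class(es): {empty}")
    head = graph.output
    width = graph[head.inputs[0]].out_channels if head.kind == "activation" else head.out_channels
    if width != len(manifest.classes):
        raise ValueError(
            f"head width {width} != class count {len(manifest.classes)}"
        )


def train_classifier(graph: ModelGraph, data: DatasetManifest,
                     config: KDConfig | None = None,
                     arrays: tuple[np.ndarray, np.ndarray] | None = None,
                     ) -> tuple[Model, dict]:
    """Standard supervised training with cross-entropy and Adam.

    ``arrays`` may carry preloaded ``(X_train, y_train)`` to skip file I/O.
    Returns the trained model and a per-epoch history of loss and accuracy.
    """
    config = config or KDConfig()
    _check_data(data, graph)
    x, y = arrays if arrays is not None else load_arrays(data, "train")
    n_classes = len(data.classes)
    model = Model(graph, seed=config.seed)
    lr = config.learning_rate if config.learning_rate is not None else BASE_LEARNING_RATE
    opt = Adam(model, learning_rate=lr)
    rng = np.random.default_rng([config.seed, 7919])
    history = {"loss": [], "accuracy": []}
    for _ in range(config.epochs):
        order = rng.permutation(len(x))
        losses, correct = [], 0
        for start in range(0, len(x), config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = x[idx], y[idx]
            logits = model.logits(xb, training=True)
            probs = tempered_softmax(logits, 1.0)
            losses.append(hard_loss(probs, yb) * len(idx))
            correct += int((probs.argmax(axis=1) == yb).sum())
            grad = (probs - _one_hot(yb, n_classes)) / len(idx)
            opt.step(model.backward(grad))
        history["loss"].append(sum(losses) / len(x))
        history["accuracy"].append(correct / len(x))
    return model, history


def distill(teacher: Model, student_graph: ModelGraph, data: DatasetManifest,
            config: KDConfig | None = None,
            arrays: tuple[np.ndarray, np.ndarray] | None = None,
            ) -> tuple[Model, dict]:
    """Train a student against a frozen teacher with the mixed KD objective.

    Per batch: soft targets = tempered softmax of the teacher's logits at τ,
    soft predictions = tempered softmax of the student's logits at τ, hard
    predictions at τ=1; the gradient of Total = Soft·(1−α) + Hard·α flows
    through the student only.  Teacher logits are precomputed once since the
    teacher never changes.
    """
    config = config or KDConfig()
    _check_data(data, student_graph)
    x, y = arrays if arrays is not None else load_arrays(data, "train")
    n_classes = len(data.classes)
    t_logits_all = _batched_logits(teacher, x, config.batch_size)
    if t_logits_all.shape[1] != n_classes:
        raise ValueError("teacher and student class widths differ")
    tau, alpha = config.temperature, config.alpha
    soft_targets_all = tempered_softmax(t_logits_all, tau)
    student = Model(student_graph, seed=config.seed)
    lr = config.learning_rate if config.learning_rate is not None else KD_LEARNING_RATE
    opt = Adam(student, learning_rate=lr)
    rng = np.random.default_rng([config.seed, 7919])
    history = {"loss": [], "soft_loss": [], "hard_loss": [], "accuracy": []}
    for _ in range(config.epochs):
        order = rng.permutation(len(x))
        tot, soft_sum, hard_sum, correct = [], [], [], 0
        for start in range(0, len(x), config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = x[idx], y[idx]
            logits = student.logits(xb, training=True)
            soft_pred = tempered_softmax(logits, tau)
            hard_pred = tempered_softmax(logits, 1.0)
            soft_t = soft_targets_all[idx]
            s_l = soft_loss(soft_t, soft_pred)
            h_l = hard_loss(hard_pred, yb)
            tot.append(total_loss(s_l, h_l, alpha) * len(idx))
            soft_sum.append(s_l * len(idx))
            hard_sum.append(h_l * len(idx))
            correct += int((hard_pred.argmax(axis=1) == yb).sum())
            grad = (
                alpha * (hard_pred - _one_hot(yb, n_classes))
                + (1 - alpha) / tau * (soft_pred - soft_t)
            ) / len(idx)
            opt.step(student.backward(grad))
        n = len(x)
        history["loss"].append(sum(tot) / n)
        history["soft_loss"].append(sum(soft_sum) / n)
        history["hard_loss"].append(sum(hard_sum) / n)
        history["accuracy"].append(correct / n)
    return student, history


def _batched_logits(model: Model, x: np.ndarray, batch_size: int) -> np.ndarray:
    outs = [
        model.logits(x[s : s + batch_size], training=False)
        for s in range(0, len(x), batch_size)
    ]
    return np.concatenate(outs, axis=0)
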