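"""Activation functions.

SeLU is the self-normalizing activation central to the residual block: it
scales positive inputs by λ and maps negative inputs onto a saturating
exponential with amplitude λ·β, using the canonical constants (λ≈1.0507,
β≈1.6732) that make unit-variance activations a fixed point of deep
feed-forward propagation.
"""

from __future__ import annotations

import numpy as np

#: canonical self-normalizing constants (full precision; 1.6732 / 1.0507 to 4 dp)
SELU_BETA = 1.6732632423543772848170429916717
SELU_LAMBDA = 1.0507009873554804934193349852946


def _check_finite(x) -> np.ndarray:
    arr = np.asarray(x)
    if not np.issubdtype(arr.dtype, np.floating):
        arr = arr.astype(float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("activation input must be finite")
    return arr


def selu(x):
    """Scaled exponential linear unit: λ·x for x>0, λ·β·(e^x − 1) for x≤0."""
    arr = _check_finite(x)
    out = np.where(arr > 0, SELU_LAMBDA * arr, SELU_LAMBDA * SELU_BETA * np.expm1(arr))
    return out if out.ndim else float(out)


def selu_grad(x):
    arr = _check_finite(x)
    out = np.where(arr > 0, SELU_LAMBDA, SELU_LAMBDA * SELU_BETA * np.exp(arr))
    return out if out.ndim else float(out)


def relu(x):
    """max(0, x)."""
    arr = _check_finite(x)
    out = np.maximum(arr, 0.0)
    return out if out.ndim else float(out)


def relu_grad(x):
    arr = _check_finite(x)
    out = (arr > 0).astype(float)
    return out if out.ndim else float(out)


def sigmoid(x):
    arr = np.asarray(x)
    # tanh form is overflow-free in both tails
    out = 0.5 * (1.0 + np.tanh(0.5 * arr))
    return out if out.ndim else float(out)


def sigmoid_grad(x):
    s = np.asarray(sigmoid(x))
    out = s * (1.0 - s)
    return out if out.ndim else float(out)


def swish(x):
    """x · sigmoid(x) (SiLU)."""
    arr = np.asarray(x)
    out = arr * np.asarray(sigmoid(arr))
    return out if out.ndim else float(out)


def swish_grad(x):
    arr = np.asarray(x)
    s = np.asarray(sigmoid(arr))
    out = s + arr * s * (1.0 - s)
    return out if out.ndim else float(out)


FORWARD = {"selu": selu, "relu": relu, "swish": swish, "sigmoid": sigmoid}
GRAD = {"selu": selu_grad, "relu": relu_grad, "swish": swish_grad, "sigmoid": sigmoid_grad}
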