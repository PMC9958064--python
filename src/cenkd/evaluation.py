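"""Confusion-matrix metrics and combined performance/cost reporting.

Per-class metrics are one-vs-rest: for class ``c``, TP is the diagonal
entry, FP the rest of its column, FN the rest of its row and TN everything
else, giving

    Acc = (TP + TN) / all samples        Pr = TP / (TP + FP)
    Rc  = TP / (TP + FN)                 F1 = 2·Pr·Rc / (Pr + Rc)

The overall row weights each per-class Pr/Rc/F1 by its validation count
(micro-style averaging; the overall F1 is the weighted mean of per-class F1
values, not recomputed from overall Pr/Rc), while overall accuracy is total
correct over total samples.  Percentages round half-up to two decimals for
display.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .cost import FlopsReport, profile
from .data import DatasetManifest, load_arrays

METRICS = ("acc", "pr", "rc", "f1")


def round_half_up(value: float, decimals: int = 2) -> float:
    """Decimal round-half-up, matching how printed tables are rounded."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def confusion(true_labels, predicted_labels, n_classes: int) -> np.ndarray:
    """N×N count matrix; rows are true classes, columns predictions."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape:
        raise ValueError("label sequences must have equal length")
    if t.size and (t.min() < 0 or t.max() >= n_classes or p.min() < 0 or p.max() >= n_classes):
        raise ValueError("label outside [0, n_classes)")
    cm = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(cm, (t, p), 1)
    return cm


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean 2·Pr·Rc/(Pr+Rc); accepts either fractions or percents."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


@dataclass
class MetricsReport:
    """Per-class and overall classification metrics, percent scale."""

    classes: list[str]
    counts: list[int]  # validation samples per class
    per_class: dict[str, list[float | None]]  # metric -> per-class values (%)
    overall: dict[str, float] = field(default_factory=dict)  # metric -> value (%)
    cost: FlopsReport | None = None

    def to_frame(self, rounded: bool = True) -> pd.DataFrame:
        def fmt(v):
            if v is None:
                return float("nan")
            return round_half_up(v) if rounded else v

        rows = []
        for i, name in enumerate(self.classes):
            rows.append(
                {"class": name, "validation_samples": self.counts[i],
                 **{m: fmt(self.per_class[m][i]) for m in METRICS}}
            )
        rows.append(
            {"class": "Overall", "validation_samples": int(sum(self.counts)),
             **{m: fmt(self.overall.get(m)) for m in METRICS}}
        )
        return pd.DataFrame(rows)

    def __str__(self) -> str:
        out = self.to_frame().to_string(index=False)
        if self.cost is not None:
            out += (
                f"\nparams: {self.cost.n_params:,}  "
                f"FLOPs: {self.cost.total_flops:,} ({self.cost.gflops:.4f} GFLOPs)"
            )
        return out


def per_class_metrics(cm: np.ndarray, classes: list[str] | None = None) -> MetricsReport:
    """One-vs-rest Acc/Pr/Rc/F1 per class from a confusion matrix.

    A zero denominator leaves the metric undefined (``None``) with a warning
    rather than silently reporting 0.
    """
    cm = np.asarray(cm)
    n = cm.shape[0]
    if cm.size == 0 or cm.sum() == 0:
        raise ValueError("empty confusion matrix")
    names = classes if classes is not None else [f"class_{i}" for i in range(n)]
    total = int(cm.sum())
    per: dict[str, list[float | None]] = {m: [] for m in METRICS}
    for c in range(n):
        tp = int(cm[c, c])
        fp = int(cm[:, c].sum()) - tp
        fn = int(cm[c, :].sum()) - tp
        tn = total - tp - fp - fn
        per["acc"].append(100.0 * (tp + tn) / total)
        pr = rc = None
        if tp + fp > 0:
            pr = 100.0 * tp / (tp + fp)
        else:
            warnings.warn(f"precision undefined for class {names[c]} (no predictions)")
        if tp + fn > 0:
            rc = 100.0 * tp / (tp + fn)
        else:
            warnings.warn(f"recall undefined for class {names[c]} (no true samples)")
        if pr is None or rc is None or pr + rc == 0:
            per["f1"].append(None if pr is None or rc is None else 0.0)
        else:
            per["f1"].append(f1_score(pr, rc))
        per["pr"].append(pr)
        per["rc"].append(rc)
    counts = [int(cm[c, :].sum()) for c in range(n)]
    report = MetricsReport(list(names), counts, per)
    report.overall = overall_metrics(report, cm=cm)
    return report


def overall_metrics(report: MetricsReport, cm: np.ndarray | None = None) -> dict[str, float]:
    """Validation-count-weighted overall row.

    Pr/Rc/F1 are weighted means of the per-class values; overall accuracy is
    total correct over total samples when the confusion matrix is available,
    else the weighted mean of per-class recall (identical for single-label
    data).
    """
    weights = np.asarray(report.counts, dtype=float)
    if weights.sum() == 0:
        raise ValueError("no validation samples")
    out: dict[str, float] = {}
    for m in ("pr", "rc", "f1"):
        vals = report.per_class[m]
        pairs = [(v, w) for v, w in zip(vals, weights) if v is not None]
        if pairs:
            vs, ws = zip(*pairs)
            out[m] = float(np.dot(vs, ws) / np.sum(ws))
    if cm is not None:
        out["acc"] = 100.0 * float(np.trace(cm)) / float(cm.sum())
    elif "rc" in out:
        out["acc"] = out["rc"]
    return out


def evaluate(model, manifest: DatasetManifest, batch_size: int = 64) -> MetricsReport:
    """Run validation inference, compute metrics and attach the cost profile."""
    val = manifest.subset("validation")
    if not val:
        raise ValueError("manifest has an empty validation split")
    x, y = load_arrays(manifest, "validation")
    pred = model.predict(x, batch_size=batch_size)
    cm = confusion(y, pred, len(manifest.classes))
    report = per_class_metrics(cm, manifest.classes)
    report.cost = profile(model.graph)
    return report
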