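"""Instance-level evaluation: confusion matrix, the metric suite
(accuracy, per-class accuracy, sensitivity, specificity, precision, F1),
key-instance-detection statistics, and selection montages.

Two averaging modes for the binary-style metrics on the 3-class task:

* ``macro_ovr`` (default): each class against the rest, unweighted mean.
* ``disease_binary``: collapse {benign, cancer} vs normal and compute plain
  binary metrics with "diseased" as the positive class.

Every report states its mode; the two are not comparable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .losses import OrdinalCutpoints
from .network import OrdinalCNN

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "predict_class",
    "metrics_from_confusion",
    "evaluate",
    "kid_stats",
    "render_selection",
]


@dataclass
class ConfusionMatrix:
    """3x3 counts; rows are true classes, columns predicted classes."""

    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (3, 3) or (self.counts < 0).any():
            raise ValueError("confusion matrix must be 3x3 with non-negative counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class MetricsReport:
    accuracy: float
    per_class_accuracy: List[float]  # recall per true class; NaN if class absent
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    averaging_mode: str

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "per_class_accuracy": self.per_class_accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "f1": self.f1,
            "averaging_mode": self.averaging_mode,
        }


def predict_class(score, cuts: Optional[OrdinalCutpoints] = None):
    """Class index from a head output.

    Scalar score(s): 0 below b1, 1 in [b1, b2), 2 at or above b2.
    Probability row(s): argmax, ties resolved to the lower class.
    """
    arr = np.asarray(score)
    if arr.ndim >= 1 and arr.shape[-1] == 3 and cuts is None:
        pred = arr.argmax(axis=-1)
        return int(pred) if arr.ndim == 1 else pred
    if cuts is None:
        raise ValueError("scalar scores need cutpoints")
    pred = (arr >= cuts.b1).astype(int) + (arr >= cuts.b2).astype(int)
    return int(pred) if arr.ndim == 0 else pred


def _nanmean(values: Sequence[float]) -> float:
    vals = [v for v in values if not math.isnan(v)]
    return float(np.mean(vals)) if vals else float("nan")


def _binary_rates(tp: int, fn: int, fp: int, tn: int) -> Tuple[float, float, float]:
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    prec = tp / (tp + fp) if tp + fp else float("nan")
    return sens, spec, prec


def metrics_from_confusion(cm: ConfusionMatrix, mode: str = "macro_ovr") -> MetricsReport:
    """Compute the metric suite from a confusion matrix.

    Under ``macro_ovr`` undefined one-vs-rest values (empty class) are
    excluded from the macro mean; F1 is the harmonic mean of the report's
    aggregated precision and sensitivity.
    """
    c = cm.counts
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    accuracy = float(np.trace(c)) / total
    row = c.sum(axis=1)
    per_class = [float(c[i, i]) / row[i] if row[i] else float("nan") for i in range(3)]
    if mode == "macro_ovr":
        sens_l, spec_l, prec_l = [], [], []
        for i in range(3):
            tp = int(c[i, i])
            fn = int(row[i] - tp)
            fp = int(c[:, i].sum() - tp)
            tn = int(total - tp - fn - fp)
            s, sp, p = _binary_rates(tp, fn, fp, tn)
            sens_l.append(s)
            spec_l.append(sp)
            prec_l.append(p)
        sens, spec, prec = _nanmean(sens_l), _nanmean(spec_l), _nanmean(prec_l)
    elif mode == "disease_binary":
        tp = int(c[1:, 1:].sum())
        fn = int(c[1:, 0].sum())
        fp = int(c[0, 1:].sum())
        tn = int(c[0, 0])
        sens, spec, prec = _binary_rates(tp, fn, fp, tn)
    else:
        raise ValueError("mode must be 'macro_ovr' or 'disease_binary'")
    if prec > 0 and sens > 0:
        f1 = 2 * prec * sens / (prec + sens)
    else:
        f1 = 0.0 if not (math.isnan(prec) or math.isnan(sens)) else float("nan")
    return MetricsReport(
        accuracy=accuracy,
        per_class_accuracy=per_class,
        sensitivity=sens,
        specificity=spec,
        precision=prec,
        f1=f1,
        averaging_mode=mode,
    )


def evaluate(
    net: OrdinalCNN,
    cuts: Optional[OrdinalCutpoints],
    test_set: Sequence,
    mode: str = "macro_ovr",
) -> Tuple[ConfusionMatrix, MetricsReport]:
    """Predict every labeled patch and tabulate the metric suite."""
    if not test_set:
        raise ValueError("empty test set")
    patches = np.stack([p for p, _ in test_set])
    labels = np.array([y for _, y in test_set])
    out = net.forward(patches)
    if net.spec.head == "ordinal_scalar":
        preds = predict_class(out, cuts)
    else:
        preds = out.argmax(axis=-1)
    counts = np.zeros((3, 3), dtype=np.int64)
    for y, p in zip(labels, preds):
        counts[int(y), int(p)] += 1
    cm = ConfusionMatrix(counts=counts)
    return cm, metrics_from_confusion(cm, mode)


def kid_stats(history: Sequence, bags: Sequence) -> Dict[int, dict]:
    """Key-instance-detection quality per epoch, over positive bags only.

    For each epoch: the mean number of true positives among the selected
    instances (the S of the E/K/S logs) and the selection precision
    ``sum(S) / (k * n_positive_bags)``.  Requires hidden instance labels.
    """
    positive_ids = {bag.bag_id for bag in bags if bag.label > 0}
    epochs: Dict[int, list] = {}
    for rec in history:
        if rec.bag_id not in positive_ids:
            continue
        if rec.n_true_positive is None:
            raise ValueError("selection history carries no hidden-label counts")
        epochs.setdefault(rec.epoch, []).append((rec.n_true_positive, len(rec.selected_indices)))
    if not epochs:
        raise ValueError("no positive-bag selections in history")
    out = {}
    for epoch, items in sorted(epochs.items()):
        s_total = sum(s for s, _ in items)
        k_total = sum(k for _, k in items)
        out[epoch] = {
            "mean_s": s_total / len(items),
            "precision": s_total / k_total,
            "n_bags": len(items),
        }
    return out


def _draw_outline(tile: np.ndarray, color: Tuple[float, float, float], width: int = 3) -> None:
    for ch in range(3):
        tile[:width, :, ch] = color[ch]
        tile[-width:, :, ch] = color[ch]
        tile[:, :width, ch] = color[ch]
        tile[:, -width:, ch] = color[ch]


def render_selection(
    bag,
    record,
    path: Optional[str] = None,
    tile_side: int = 64,
    grid_cols: int = 7,
) -> np.ndarray:
    """Montage of a bag with its selected key instances outlined.

    Correctly selected instances (hidden label == bag label) are outlined in
    red, incorrect ones in blue; without hidden labels a neutral yellow is
    used.  Returns an RGB uint8 array; written as PNG if ``path`` is given.
    """
    from skimage.transform import resize as _sk_resize

    n = len(bag.instances)
    if any(i < 0 or i >= n for i in record.selected_indices):
        raise ValueError("selection record does not match this bag")
    rows = (n + grid_cols - 1) // grid_cols
    canvas = np.zeros((rows * tile_side, grid_cols * tile_side, 3), dtype=np.float32)
    selected = set(record.selected_indices)
    for i, inst in enumerate(bag.instances):
        r, c = divmod(i, grid_cols)
        tile = _sk_resize(inst.pixels, (tile_side, tile_side), order=1, anti_aliasing=True)
        tile = np.clip(tile, 0, 1)[..., None].repeat(3, axis=-1).astype(np.float32)
        if i in selected:
            if inst.hidden_label is None:
                color = (1.0, 0.9, 0.1)  # neutral: no ground truth
            elif inst.hidden_label == bag.label:
                color = (1.0, 0.1, 0.1)  # true key instance
            else:
                color = (0.15, 0.3, 1.0)  # false key instance
            _draw_outline(tile, color)
        canvas[r * tile_side : (r + 1) * tile_side, c * tile_side : (c + 1) * tile_side] = tile
    img = (canvas * 255).round().astype(np.uint8)
    if path is not None:
        import imageio.v3 as iio

        iio.imwrite(path, img)
    return img


def report_to_json(cm: ConfusionMatrix, report: MetricsReport, path: str, config_echo: dict) -> None:
    """Write the evaluation report (matrix + metrics + config echo)."""
    payload = {
        "confusion_matrix": cm.counts.tolist(),
        "metrics": report.to_dict(),
        "config": config_echo,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
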