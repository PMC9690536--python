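"""Per-instance losses against the bag label.

The default is an all-threshold cumulative-logistic ordinal loss on the
scalar head: with trainable cutpoints b1 < b2 partitioning the score axis
into the three ordered classes,

    L(s, y) = sum_{c in {0,1}} softplus( z_c * (s - b_{c+1}) ),
    z_c = +1 if y <= c else -1,

i.e. each class boundary contributes a logistic penalty when the score
falls on the wrong side of its cutpoint.  The loss is differentiable in the
score and in the cutpoints, is zero only in the limit of a score deep
inside the correct class region, and respects class order: at any score the
loss of an adjacent class never exceeds that of a more distant class.

A squared-error variant (s - y)^2 and the 3-way softmax cross-entropy
baseline are provided for the ablation comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import expit

__all__ = [
    "OrdinalCutpoints",
    "LossVector",
    "LOSS_CHOICES",
    "ordinal_uncertainty_loss",
    "ordinal_uncertainty_loss_grad",
    "squared_error_ordinal_loss",
    "cross_entropy_loss",
    "bag_loss_vector",
]

LOSS_CHOICES = ("min_uncertainty_ordinal", "squared_error_ordinal", "cross_entropy")

_CE_FLOOR = 1e-12


def _softplus(x):
    return np.logaddexp(0.0, x)


@dataclass
class OrdinalCutpoints:
    """Trainable class-boundary thresholds for the scalar head.

    Parameterised as ``b1`` and ``delta`` with ``b2 = b1 + softplus(delta)``
    so the ordering b2 > b1 holds for any parameter values.  Defaults put
    the cutpoints at the midpoints between consecutive class indices
    (0.5 and 1.5), matching a consecutive-integer mapping of the classes.
    """

    b1: float = 0.5
    delta: float = 0.5413248546129181  # softplus(delta) = 1  ->  b2 = 1.5

    @property
    def b2(self) -> float:
        return self.b1 + float(_softplus(self.delta))

    @classmethod
    def from_boundaries(cls, b1: float, b2: float) -> "OrdinalCutpoints":
        if not b2 > b1:
            raise ValueError("cutpoints must satisfy b2 > b1")
        gap = b2 - b1
        # invert softplus: delta = log(e^gap - 1), stable for small/large gap
        delta = gap + math.log1p(-math.exp(-gap))
        return cls(b1=b1, delta=delta)

    def boundaries(self) -> np.ndarray:
        return np.array([self.b1, self.b2])


@dataclass
class LossVector:
    """Per-instance loss values of one bag, in bag order."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("loss values must be finite")
        if np.any(self.values < 0):
            raise ValueError("loss values must be non-negative")

    def __len__(self):
        return len(self.values)


def _signs(label: int) -> np.ndarray:
    if label not in (0, 1, 2):
        raise ValueError(f"label must be in {{0,1,2}}, got {label!r}")
    # z_c = +1 when the true class lies at or below boundary c, else -1
    return np.array([1.0 if label <= c else -1.0 for c in (0, 1)])


def ordinal_uncertainty_loss(score, label: int, cuts: OrdinalCutpoints):
    """All-threshold ordinal loss of score(s) against an ordinal label.

    Accepts a scalar or an array of scores; returns matching shape.
    """
    s = np.asarray(score, dtype=np.float64)
    if not np.all(np.isfinite(s)):
        raise ValueError("score must be finite")
    z = _signs(label)
    b = cuts.boundaries()
    terms = _softplus(z * (s[..., None] - b))
    out = terms.sum(axis=-1)
    return float(out) if np.isscalar(score) or s.ndim == 0 else out


def ordinal_uncertainty_loss_grad(score, label: int, cuts: OrdinalCutpoints):
    """Loss and analytic gradients (d/ds, d/db1, d/ddelta).

    Vectorized over scores; gradient arrays match the score shape for d/ds,
    while the cutpoint gradients are summed over instances.
    """
    s = np.asarray(score, dtype=np.float64)
    z = _signs(label)
    b = cuts.boundaries()
    u = z * (s[..., None] - b)
    sig = expit(u)  # d softplus(u) / du
    ds = (z * sig).sum(axis=-1)
    # b2 = b1 + softplus(delta): both boundaries move with b1
    db = -(z * sig)
    db1 = float(db.sum())
    ddelta = float(db[..., 1].sum() * expit(cuts.delta))
    loss = _softplus(u).sum(axis=-1)
    return loss, ds, db1, ddelta


def squared_error_ordinal_loss(score, label: int, cuts: Optional[OrdinalCutpoints] = None):
    """Simplest ordinal surrogate: (s - y)^2 with the class index as target."""
    if label not in (0, 1, 2):
        raise ValueError(f"label must be in {{0,1,2}}, got {label!r}")
    s = np.asarray(score, dtype=np.float64)
    out = (s - label) ** 2
    return float(out) if np.isscalar(score) or s.ndim == 0 else out


def cross_entropy_loss(probs, label: int):
    """-log p[label] for a probability row (or rows) of length 3."""
    p = np.asarray(probs, dtype=np.float64)
    if p.shape[-1] != 3:
        raise ValueError("expected probability vectors of length 3")
    if not np.allclose(p.sum(axis=-1), 1.0, atol=1e-5):
        raise ValueError("probabilities must sum to 1")
    if label not in (0, 1, 2):
        raise ValueError(f"label must be in {{0,1,2}}, got {label!r}")
    out = -np.log(np.maximum(p[..., label], _CE_FLOOR))
    return float(out) if p.ndim == 1 else out


def bag_loss_vector(net, bag, loss: str, cuts: Optional[OrdinalCutpoints] = None) -> LossVector:
    """Loss of every instance in a bag against the bag label, in bag order."""
    from .network import forward_bag  # local import to avoid cycles

    if loss not in LOSS_CHOICES:
        raise ValueError(f"loss must be one of {LOSS_CHOICES}")
    out = forward_bag(net, bag)
    if loss == "cross_entropy":
        if net.spec.head != "softmax3":
            raise ValueError("cross_entropy requires the softmax3 head")
        values = cross_entropy_loss(out, bag.label)
    else:
        if net.spec.head != "ordinal_scalar":
            raise ValueError(f"{loss} requires the ordinal_scalar head")
        if loss == "min_uncertainty_ordinal":
            if cuts is None:
                raise ValueError("ordinal loss needs cutpoints")
            values = ordinal_uncertainty_loss(out, bag.label, cuts)
        else:
            values = squared_error_ordinal_loss(out, bag.label)
    return LossVector(values=np.atleast_1d(values))
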