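"""Key-instance training loop.

Per bag and per visit: score every instance under the current parameters,
rank instances by their loss against the bag label, select the k
minimum-loss "key instances", assign them the bag label, and take one Adam
step on the mean of their losses.  Selection is redone from scratch at every
visit, so the identity of the key instances is uncertain early on and is
iteratively refined as the network improves.

Also provides the ordered-binary-decomposition baseline (one binary scorer
per class boundary, combined by counting "greater" votes), which isolates
the value of modelling the ordinal classes directly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from numba import njit
from scipy.special import expit

from .bag_builder import Bag
from .losses import (
    LOSS_CHOICES,
    LossVector,
    OrdinalCutpoints,
    bag_loss_vector,
    ordinal_uncertainty_loss_grad,
)
from .network import NetworkSpec, OrdinalCNN, build_network

__all__ = [
    "TrainConfig",
    "SelectionRecord",
    "Adam",
    "select_key_instances",
    "train_step",
    "train",
    "train_omil_baseline",
    "OmilBaseline",
]


@dataclass
class TrainConfig:
    k: int = 4
    epochs: int = 1
    learning_rate: float = 1e-4
    weight_decay: float = 5e-4
    adam_eps: float = 1e-6
    adam_betas: Tuple[float, float] = (0.9, 0.99)
    loss: str = "squared_error_ordinal"
    seed: int = 0

    def validate(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.learning_rate < 0 or self.weight_decay < 0 or self.adam_eps <= 0:
            raise ValueError("rates must be non-negative (eps positive)")
        if self.loss not in LOSS_CHOICES:
            raise ValueError(f"loss must be one of {LOSS_CHOICES}")


@dataclass
class SelectionRecord:
    """What was selected in one training step (the data behind E/K/S plots)."""

    epoch: int
    bag_id: str
    selected_indices: List[int]
    selected_losses: List[float]
    n_true_positive: Optional[int] = None  # S: selected with hidden label == bag label
    min_unselected_loss: Optional[float] = None
    n_instances: int = 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "epoch": self.epoch,
                "bag_id": self.bag_id,
                "selected_indices": self.selected_indices,
                "selected_losses": self.selected_losses,
                "n_true_positive": self.n_true_positive,
                "min_unselected_loss": self.min_unselected_loss,
                "n_instances": self.n_instances,
            }
        )


@njit(cache=False, fastmath=True)
def _adam_update(p, m, v, g, lr, b1, b2, eps, wd, t):  # pragma: no cover - numba
    bc1 = 1.0 - b1**t
    bc2 = 1.0 - b2**t
    for i in range(p.size):
        mi = b1 * m[i] + (1.0 - b1) * g[i]
        vi = b2 * v[i] + (1.0 - b2) * g[i] * g[i]
        m[i] = mi
        v[i] = vi
        p[i] -= lr * ((mi / bc1) / (np.sqrt(vi / bc2) + eps) + wd * p[i])


class Adam:
    """Adam with decoupled weight decay, updating parameter arrays in place."""

    def __init__(self, params: Dict[str, np.ndarray], cfg: TrainConfig):
        self.params = params
        self.cfg = cfg
        self.t = 0
        self.m = {k: np.zeros(v.size, dtype=np.float32) for k, v in params.items()}
        self.v = {k: np.zeros(v.size, dtype=np.float32) for k, v in params.items()}

    def step(self, grads: Dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.cfg.adam_betas
        for key, g in grads.items():
            p = self.params[key].reshape(-1)
            _adam_update(
                p,
                self.m[key],
                self.v[key],
                np.ascontiguousarray(g, dtype=np.float32).reshape(-1),
                self.cfg.learning_rate,
                b1,
                b2,
                self.cfg.adam_eps,
                self.cfg.weight_decay,
                self.t,
            )


def select_key_instances(losses, k: int) -> List[int]:
    """Indices of the k smallest losses, in order of increasing loss.

    Ties are broken by the lower instance index (stable sort).
    """
    values = losses.values if isinstance(losses, LossVector) else np.asarray(losses, dtype=float)
    n = len(values)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range for {n} losses")
    order = np.argsort(values, kind="stable")
    return [int(i) for i in order[:k]]


def _cut_params(cuts: OrdinalCutpoints) -> np.ndarray:
    return np.array([cuts.b1, cuts.delta], dtype=np.float32)


def _sync_cuts(cuts: OrdinalCutpoints, arr: np.ndarray) -> None:
    cuts.b1 = float(arr[0])
    cuts.delta = float(arr[1])


def _selected_gradients(net, cuts, pixels, label, k, loss):
    """Forward the selected instances with cache; return grads + cut grads."""
    out = net.forward(pixels, want_cache=True)
    if loss == "min_uncertainty_ordinal":
        _, ds, db1, ddelta = ordinal_uncertainty_loss_grad(out, label, cuts)
        d_preact = (ds / k)[:, None]
        cut_grad = np.array([db1 / k, ddelta / k], dtype=np.float32)
    elif loss == "squared_error_ordinal":
        d_preact = (2.0 * (out - label) / k)[:, None]
        cut_grad = None
    else:  # cross_entropy on the softmax head
        onehot = np.zeros_like(out)
        onehot[:, label] = 1.0
        d_preact = (out - onehot) / k
        cut_grad = None
    grads = net.backward(d_preact)
    return grads, cut_grad


def train_step(
    net: OrdinalCNN,
    cuts: OrdinalCutpoints,
    bag: Bag,
    cfg: TrainConfig,
    optimizer: Optional[Adam] = None,
    epoch: int = 0,
) -> SelectionRecord:
    """One optimisation step on one bag.

    Scores all instances without gradients, selects the k min-loss key
    instances, then recomputes only their losses with gradients and applies
    one Adam update on the mean.  Returns the step's SelectionRecord.
    """
    cfg.validate()
    if not bag.instances:
        raise ValueError("empty bag")
    if cfg.k > len(bag.instances):
        raise ValueError(f"k={cfg.k} exceeds bag size {len(bag.instances)}")
    if optimizer is None:
        optimizer = _make_optimizer(net, cuts, cfg)
    lv = bag_loss_vector(net, bag, cfg.loss, cuts)
    selected = select_key_instances(lv, cfg.k)
    unselected = np.setdiff1d(np.arange(len(lv)), selected)
    pixels = np.stack([bag.instances[i].pixels for i in selected])
    grads, cut_grad = _selected_gradients(net, cuts, pixels, bag.label, cfg.k, cfg.loss)
    if cut_grad is not None and "cutpoints" in optimizer.params:
        grads = dict(grads)
        grads["cutpoints"] = cut_grad
    optimizer.step(grads)
    if "cutpoints" in optimizer.params:
        _sync_cuts(cuts, optimizer.params["cutpoints"])
    hidden = [bag.instances[i].hidden_label for i in selected]
    n_tp = sum(h == bag.label for h in hidden) if all(h is not None for h in hidden) else None
    return SelectionRecord(
        epoch=epoch,
        bag_id=bag.bag_id,
        selected_indices=selected,
        selected_losses=[float(lv.values[i]) for i in selected],
        n_true_positive=n_tp,
        min_unselected_loss=float(lv.values[unselected].min()) if len(unselected) else None,
        n_instances=len(lv),
    )


def _make_optimizer(net: OrdinalCNN, cuts: Optional[OrdinalCutpoints], cfg: TrainConfig) -> Adam:
    params = dict(net.params)
    if cuts is not None and cfg.loss == "min_uncertainty_ordinal":
        params["cutpoints"] = _cut_params(cuts)
    return Adam(params, cfg)


def train(
    net: OrdinalCNN,
    cuts: OrdinalCutpoints,
    bags: Sequence[Bag],
    cfg: TrainConfig,
    log_path: Optional[str] = None,
):
    """Train over seeded-shuffled bag visits for ``cfg.epochs`` epochs.

    Returns ``(net, history, trace)``: the trained network (updated in
    place), the full list of SelectionRecords, and the per-epoch mean of
    the mean selected loss.
    """
    cfg.validate()
    if not bags:
        raise ValueError("no bags to train on")
    rng = np.random.default_rng(cfg.seed)
    optimizer = _make_optimizer(net, cuts, cfg)
    history: List[SelectionRecord] = []
    trace: List[float] = []
    log_lines = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(bags))
        epoch_losses = []
        for idx in order:
            rec = train_step(net, cuts, bags[idx], cfg, optimizer=optimizer, epoch=epoch)
            history.append(rec)
            step_mean = float(np.mean(rec.selected_losses))
            epoch_losses.append(step_mean)
            if log_path is not None:
                log_lines.append(rec.to_json())
        trace.append(float(np.mean(epoch_losses)))
    if log_path is not None:
        with open(log_path, "w") as fh:
            fh.write("\n".join(log_lines) + ("\n" if log_lines else ""))
    return net, history, trace


# ---------------------------------------------------------------------------
# ordered binary decomposition baseline


@dataclass
class OmilBaseline:
    """C-1 binary scorers combined by the ordered-partition voting rule."""

    nets: List[OrdinalCNN]

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Predicted class = number of boundary scorers voting 'greater'."""
        votes = np.zeros(np.asarray(x).shape[0] if np.asarray(x).ndim == 3 else 1, dtype=int)
        for net in self.nets:
            votes += (net.forward(x) > 0).astype(int)
        return votes


def _train_binary(net: OrdinalCNN, targets_bags, cfg: TrainConfig) -> None:
    """Key-instance training of one binary scorer with logistic loss."""
    rng = np.random.default_rng(cfg.seed)
    optimizer = Adam(dict(net.params), cfg)
    for _ in range(cfg.epochs):
        order = rng.permutation(len(targets_bags))
        for idx in order:
            bag, target = targets_bags[idx]
            x = np.stack([inst.pixels for inst in bag.instances])
            s = net.forward(x)
            losses = np.logaddexp(0.0, -s) if target == 1 else np.logaddexp(0.0, s)
            k = min(cfg.k, len(losses))
            selected = select_key_instances(losses, k)
            pix = np.stack([bag.instances[i].pixels for i in selected])
            out = net.forward(pix, want_cache=True)
            d_preact = ((expit(out) - target) / k)[:, None]
            optimizer.step(net.backward(d_preact))


def train_omil_baseline(
    bags: Sequence[Bag],
    cfg: TrainConfig,
    spec: Optional[NetworkSpec] = None,
    n_classes: int = 3,
) -> OmilBaseline:
    """Train one binary key-instance scorer per class boundary.

    Boundary c relabels bags as (label > c) vs (label <= c); each scorer is
    an independent scalar-head network trained with a binary logistic loss
    under the same min-loss key-instance mechanism.  Prediction counts the
    scorers voting "greater".
    """
    cfg.validate()
    if spec is None:
        spec = NetworkSpec()
    if spec.head != "ordinal_scalar":
        raise ValueError("the decomposition baseline uses scalar-head scorers")
    nets = []
    for c in range(n_classes - 1):
        targets = [(bag, int(bag.label > c)) for bag in bags]
        pos = sum(t for _, t in targets)
        if pos == 0 or pos == len(targets):
            raise ValueError(f"boundary {c}: one side of the cut has no bags")
        net = build_network(spec, seed=cfg.seed + 17 * (c + 1))
        _train_binary(net, targets, cfg)
        nets.append(net)
    return OmilBaseline(nets=nets)
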