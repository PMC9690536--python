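"""Ablation comparisons: ordinal loss vs cross-entropy, and direct ordinal
modelling vs the ordered binary decomposition, across values of k.

Produces an accuracy grid with one row per method/loss combination and one
column per k.  In the binary decomposition each boundary scorer solves a
two-class problem, where the logistic loss and a two-class cross-entropy
coincide, so the baseline contributes a single row.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Dict, Optional, Sequence

import numpy as np

from .evaluation import evaluate
from .losses import OrdinalCutpoints
from .network import NetworkSpec, build_network
from .trainer import TrainConfig, train, train_omil_baseline

__all__ = ["ablation_report"]

ROWS = (
    "cross_entropy (direct)",
    "min_uncertainty_ordinal (direct)",
    "squared_error_ordinal (direct)",
    "binary_logistic (decomposition)",
)


def _accuracy_direct(bags, test_set, cfg: TrainConfig, spec: NetworkSpec) -> float:
    net = build_network(spec, seed=cfg.seed)
    cuts = OrdinalCutpoints() if cfg.loss != "cross_entropy" else None
    train(net, cuts, bags, cfg)
    _, report = evaluate(net, cuts, test_set)
    return report.accuracy


def _accuracy_decomposition(bags, test_set, cfg: TrainConfig, spec: NetworkSpec) -> float:
    baseline = train_omil_baseline(bags, cfg, spec=replace(spec, head="ordinal_scalar"))
    patches = np.stack([p for p, _ in test_set])
    labels = np.array([y for _, y in test_set])
    preds = baseline.predict(patches)
    return float(np.mean(preds == labels))


def ablation_report(
    bags,
    test_set,
    base_cfg: Optional[TrainConfig] = None,
    k_values: Sequence[int] = (1, 2, 3, 4, 5),
    spec: Optional[NetworkSpec] = None,
) -> Dict[str, Dict[int, float]]:
    """Instance-level test accuracy for every method/loss row and every k."""
    if base_cfg is None:
        base_cfg = TrainConfig()
    if spec is None:
        spec = NetworkSpec()
    report: Dict[str, Dict[int, float]] = {row: {} for row in ROWS}
    for k in k_values:
        ce_cfg = replace(base_cfg, k=k, loss="cross_entropy")
        report["cross_entropy (direct)"][k] = _accuracy_direct(
            bags, test_set, ce_cfg, replace(spec, head="softmax3")
        )
        for loss in ("min_uncertainty_ordinal", "squared_error_ordinal"):
            ord_cfg = replace(base_cfg, k=k, loss=loss)
            report[f"{loss} (direct)"][k] = _accuracy_direct(
                bags, test_set, ord_cfg, replace(spec, head="ordinal_scalar")
            )
        report["binary_logistic (decomposition)"][k] = _accuracy_decomposition(
            bags, test_set, replace(base_cfg, k=k), spec
        )
    return report
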