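"""Classifier metrics, checkpoint selection, and per-group reporting.

Five metrics throughout: total accuracy, per-class accuracy (recall) for each
class, balanced accuracy (the unweighted mean of per-class recalls), and mean
natural-log loss.  Accuracies are percentages reported to two decimals.
Model selection is either argmax of validation balanced accuracy or argmin of
validation log loss; a "best on test" row may be reported alongside purely as
an upper bound on predictive capability, never for selection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["MetricsReport", "compute_metrics", "select_best", "best_on_test_report"]

_CLAMP = 1e-12


@dataclass
class MetricsReport:
    """One row of the evaluation table, optionally with per-group breakdown."""

    total_accuracy: float
    per_class_accuracy: list[float]
    balanced_accuracy: float
    log_loss: float
    n_samples: int
    group_breakdown: dict[str, "MetricsReport"] = field(default_factory=dict)
    selection: Optional[dict] = None

    def as_dict(self) -> dict:
        d = {
            "total_accuracy": self.total_accuracy,
            "balanced_accuracy": self.balanced_accuracy,
            "log_loss": self.log_loss,
            "n_samples": self.n_samples,
        }
        for c, acc in enumerate(self.per_class_accuracy):
            d[f"class_{c}_accuracy"] = acc
        return d

    def to_frame(self) -> pd.DataFrame:
        rows = [{"group": "all", **self.as_dict()}]
        rows += [{"group": g, **r.as_dict()} for g, r in self.group_breakdown.items()]
        return pd.DataFrame(rows)

    def to_json(self, path) -> None:
        payload = self.as_dict()
        payload["groups"] = {g: r.as_dict() for g, r in self.group_breakdown.items()}
        if self.selection is not None:
            payload["selection"] = self.selection
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def compute_metrics(
    predicted_probs: np.ndarray,
    labels: np.ndarray,
    groups: Optional[Sequence] = None,
) -> MetricsReport:
    """Accuracy/log-loss report from row-stochastic probabilities.

    Predictions are the argmax of each row (ties resolve to the lower class
    index); balanced accuracy is the unweighted mean of per-class recalls;
    log loss is ``-mean(ln p[true])`` with probabilities clamped at 1e-12.
    Accuracies are percentages rounded to two decimals.
    """
    p = np.asarray(predicted_probs, dtype=float)
    y = np.asarray(labels, dtype=int)
    if p.ndim != 2 or p.shape[0] == 0:
        raise ValueError("predicted_probs must be a nonempty (n, K) array")
    if y.shape != (p.shape[0],):
        raise ValueError("labels must match the number of rows")
    n, k = p.shape
    pred = np.argmax(p, axis=1)

    total = 100.0 * np.mean(pred == y)
    per_class = []
    for c in range(k):
        mask = y == c
        per_class.append(100.0 * np.mean(pred[mask] == c) if mask.any() else float("nan"))
    balanced = float(np.nanmean(per_class))
    ll = float(-np.mean(np.log(np.clip(p[np.arange(n), y], _CLAMP, 1.0))))

    report = MetricsReport(
        total_accuracy=round(float(total), 2),
        per_class_accuracy=[round(float(a), 2) for a in per_class],
        balanced_accuracy=round(balanced, 2),
        log_loss=ll,
        n_samples=n,
    )
    if groups is not None:
        tags = np.asarray(groups, dtype=object)
        if tags.shape != (n,):
            raise ValueError("groups must give one tag per sample")
        for g in pd.unique(tags):
            mask = tags == g
            report.group_breakdown[str(g)] = compute_metrics(p[mask], y[mask])
    return report


def select_best(
    checkpoint_metrics: Sequence[MetricsReport],
    criterion: str = "balanced_accuracy",
) -> int:
    """Index of the best checkpoint; ties resolve to the earliest epoch.

    ``balanced_accuracy`` selects the maximum, ``log_loss`` the minimum.
    """
    if len(checkpoint_metrics) == 0:
        raise ValueError("need at least one checkpoint")
    if criterion == "balanced_accuracy":
        values = [m.balanced_accuracy for m in checkpoint_metrics]
        best = max(values)
    elif criterion == "log_loss":
        values = [-m.log_loss for m in checkpoint_metrics]
        best = max(values)
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    return int(next(i for i, v in enumerate(values) if v == best))


def best_on_test_report(
    validation_metrics: Sequence[MetricsReport],
    test_metrics: Sequence[MetricsReport],
    criterion: str = "balanced_accuracy",
) -> pd.DataFrame:
    """Two clearly labeled rows: best-on-validation and best-on-test.

    The best-on-test row is informational only (an upper bound on predictive
    capability); pipelines must select on validation.
    """
    if len(validation_metrics) != len(test_metrics):
        raise ValueError("need one test report per validation checkpoint")
    i_val = select_best(validation_metrics, criterion)
    i_test = select_best(test_metrics, criterion)
    rows = [
        {"selected_on": "validation", "checkpoint": i_val, **test_metrics[i_val].as_dict()},
        {"selected_on": "test", "checkpoint": i_test, **test_metrics[i_test].as_dict()},
    ]
    return pd.DataFrame(rows)
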