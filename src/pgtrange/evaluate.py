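"""Range-shift error metrics and bootstrap confidence intervals.

Two complementary metrics quantify a model on a prediction set
{(y_i, ŷ_{i,j})}, where y_i is the i-th true air-cavity thickness (mm),
ŷ_{i,j} its j-th prediction, M_i the number of predictions per cavity and
N the number of distinct cavity thicknesses present:

* RMSE — root mean squared error over all individual predictions:
  sqrt( Σ_i Σ_j (ŷ_{i,j} − y_i)² / Σ_i M_i ).  Rewards per-spot precision.
* MRSE (mean range-shift error) —
  (1/N) Σ_i | (1/M_i) Σ_j ŷ_{i,j} − y_i |.
  Rewards aggregate accuracy: symmetric per-spot errors cancel inside the
  per-cavity average, mirroring the clinical use of pooled spot
  predictions to detect a delivery deviation.

Uncertainty comes from a percentile bootstrap over spots (resampling
predictions with replacement; a replicate that loses a cavity entirely
recomputes MRSE over the cavities it retains).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["rmse", "mrse", "bootstrap_ci", "aggregate_configurations"]


def _validate(y_true, y_pred) -> tuple[np.ndarray, np.ndarray]:
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("y_true and y_pred must be 1D arrays of equal length")
    if y_true.size == 0:
        raise ValueError("empty prediction set")
    return y_true, y_pred


def rmse(y_true, y_pred) -> float:
    """Root mean squared error over all individual predictions (mm)."""
    y_true, y_pred = _validate(y_true, y_pred)
    return float(np.sqrt(np.mean((y_pred - y_true) ** 2)))


def mrse(y_true, y_pred) -> float:
    """Mean range-shift error (mm): mean over cavities of the absolute
    difference between the cavity's average prediction and its true value."""
    y_true, y_pred = _validate(y_true, y_pred)
    errors = []
    for value in np.unique(y_true):
        sel = y_true == value
        errors.append(abs(float(y_pred[sel].mean()) - value))
    return float(np.mean(errors))


_METRICS = {"rmse": rmse, "mrse": mrse}


def bootstrap_ci(
    y_true,
    y_pred,
    metric="rmse",
    B: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap confidence interval of a metric.

    Spots (individual predictions) are resampled with replacement; each
    replicate keeps its resampled cavity membership, and MRSE adapts N to
    the cavities represented in the replicate.
    """
    y_true, y_pred = _validate(y_true, y_pred)
    fn = _METRICS[metric] if isinstance(metric, str) else metric
    rng = np.random.default_rng(seed)
    n = y_true.size
    stats = np.empty(B)
    for b in range(B):
        idx = rng.integers(0, n, n)
        stats[b] = fn(y_true[idx], y_pred[idx])
    lo, hi = np.percentile(stats, [(1 - level) / 2 * 100, (1 + level) / 2 * 100])
    return float(lo), float(hi)


def aggregate_configurations(
    results: pd.DataFrame, group_by: str
) -> pd.DataFrame:
    """Median metric per setup-parameter group, per dataset.

    ``results`` is tidy with columns [feature_set, ranking, learner,
    dataset, metric, value].  ``group_by`` is one of feature_set / ranking
    / learner.  Returns a tidy table (group, dataset, metric, value) plus,
    per (group, metric), a ``cross_dataset_mean`` row ordering the groups.
    Empty groups are omitted with a warning.
    """
    if group_by not in ("feature_set", "ranking", "learner"):
        raise ValueError(f"group_by must be feature_set/ranking/learner, got {group_by!r}")
    rows = []
    for (group, metric), sub in results.groupby([group_by, "metric"], sort=True):
        sub = sub.dropna(subset=["value"])
        if sub.empty:
            warnings.warn(f"empty group {group!r} for metric {metric!r}", stacklevel=2)
            continue
        medians = sub.groupby("dataset", sort=True)["value"].median()
        for dataset, value in medians.items():
            rows.append(
                {"group": group, "dataset": dataset, "metric": metric, "value": float(value)}
            )
        rows.append(
            {
                "group": group,
                "dataset": "cross_dataset_mean",
                "metric": metric,
                "value": float(medians.mean()),
            }
        )
    return pd.DataFrame(rows, columns=["group", "dataset", "metric", "value"])
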