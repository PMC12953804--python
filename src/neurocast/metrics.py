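"""Forecast accuracy metrics and cohort-level aggregation.

MAE, RMSE and the R^2 score are computed pairwise over valid
(actual, predicted) pairs; prediction-interval spread is summarized as the
mean (optionally median) upper-lower width.  Per-patient metric rows are
aggregated across patients into signal x resolution tables per
cross-validation method, with R^2 as the primary cell value and RMSE as its
companion, the usual heatmap layout for this kind of benchmark.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .splits import PredictionTrace

__all__ = [
    "MetricRow",
    "mae",
    "rmse",
    "r2",
    "ci_spread",
    "metric_row_from_trace",
    "fold_mae_dispersion",
    "summarize_cohort",
    "heatmap_table",
]


def _paired(actual: Sequence[float], predicted: Sequence[float]):
    y = np.asarray(actual, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if len(y) != len(yhat) or len(y) == 0:
        raise ValueError("actual and predicted must be equal-length and non-empty")
    ok = np.isfinite(y) & np.isfinite(yhat)
    return y[ok], yhat[ok]


def mae(actual: Sequence[float], predicted: Sequence[float]) -> float:
    """Mean absolute error over valid pairs; NaN when no pair is valid."""
    y, yhat = _paired(actual, predicted)
    if len(y) == 0:
        return float("nan")
    return float(np.mean(np.abs(y - yhat)))


def rmse(actual: Sequence[float], predicted: Sequence[float]) -> float:
    """Root mean squared error over valid pairs; NaN when no pair is valid."""
    y, yhat = _paired(actual, predicted)
    if len(y) == 0:
        return float("nan")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def r2(actual: Sequence[float], predicted: Sequence[float]) -> float:
    """Coefficient of determination; negative when worse than the mean.

    NaN (missing) when the actuals have zero variance.
    """
    y, yhat = _paired(actual, predicted)
    if len(y) == 0:
        return float("nan")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return float("nan")
    ss_res = float(np.sum((y - yhat) ** 2))
    return 1.0 - ss_res / ss_tot


def ci_spread(trace: PredictionTrace, statistic: str = "mean") -> float:
    """Average width (upper - lower) of the trace's prediction intervals."""
    widths = (trace.entries["upper"] - trace.entries["lower"]).to_numpy(dtype=float)
    widths = widths[np.isfinite(widths)]
    if len(widths) == 0:
        return float("nan")
    if statistic == "mean":
        return float(np.mean(widths))
    if statistic == "median":
        return float(np.median(widths))
    raise ValueError("statistic must be 'mean' or 'median'")


@dataclass
class MetricRow:
    """Per (patient, signal, resolution, method, prediction type) metrics.

    Wall-clock timings are carried for logging/reporting but are
    hardware-dependent and never asserted on.
    """

    patient_id: str
    signal_name: str
    resolution: int
    method: str
    prediction_type: str
    mae: float
    rmse: float
    r2: float
    ci_spread: float
    n_predictions: int
    train_seconds: float = float("nan")
    test_seconds: float = float("nan")


def metric_row_from_trace(
    trace: PredictionTrace,
    patient_id: str,
    signal_name: str,
    resolution: int,
    train_seconds: float = float("nan"),
    test_seconds: float = float("nan"),
) -> MetricRow:
    y = trace.entries["actual"].to_numpy(dtype=float)
    yhat = trace.entries["predicted"].to_numpy(dtype=float)
    n_valid = int(np.sum(np.isfinite(y) & np.isfinite(yhat)))
    spread = ci_spread(trace) if trace.prediction_type == "interval" else float("nan")
    return MetricRow(
        patient_id=patient_id,
        signal_name=signal_name,
        resolution=resolution,
        method=trace.method,
        prediction_type=trace.prediction_type,
        mae=mae(y, yhat) if n_valid else float("nan"),
        rmse=rmse(y, yhat) if n_valid else float("nan"),
        r2=r2(y, yhat) if n_valid else float("nan"),
        ci_spread=spread,
        n_predictions=n_valid,
        train_seconds=train_seconds,
        test_seconds=test_seconds,
    )


def fold_mae_dispersion(trace: PredictionTrace) -> tuple[float, float]:
    """Mean and SD (n-1 denominator) of the per-fold MAE of a trace."""
    per_fold = trace.fold_metric(mae).to_numpy(dtype=float)
    per_fold = per_fold[np.isfinite(per_fold)]
    if len(per_fold) == 0:
        return float("nan"), float("nan")
    sd = float(np.std(per_fold, ddof=1)) if len(per_fold) > 1 else 0.0
    return float(np.mean(per_fold)), sd


GROUP_KEYS = ["signal_name", "resolution", "method", "prediction_type"]
METRIC_COLS = ["mae", "rmse", "r2", "ci_spread"]


def summarize_cohort(rows: "Iterable[MetricRow] | pd.DataFrame") -> pd.DataFrame:
    """Cross-patient mean and SD of each metric per signal/resolution/method.

    Missing metrics are excluded from their cell, never imputed;
    ``n_patients`` counts the patients contributing at least one metric.
    Returns an empty frame for empty input.
    """
    if isinstance(rows, pd.DataFrame):
        df = rows.copy()
    else:
        df = pd.DataFrame([asdict(r) for r in rows])
    if df.empty:
        cols = GROUP_KEYS + ["n_patients"]
        for m in METRIC_COLS:
            cols += [f"{m}_mean", f"{m}_sd"]
        return pd.DataFrame(columns=cols)
    out = []
    for keys, group in df.groupby(GROUP_KEYS, sort=True):
        rec = dict(zip(GROUP_KEYS, keys))
        rec["n_patients"] = group["patient_id"].nunique()
        for m in METRIC_COLS:
            vals = group[m].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            rec[f"{m}_mean"] = float(np.mean(vals)) if len(vals) else float("nan")
            if len(vals) > 1:
                rec[f"{m}_sd"] = float(np.std(vals, ddof=1))
            elif len(vals) == 1:
                rec[f"{m}_sd"] = 0.0
            else:
                rec[f"{m}_sd"] = float("nan")
        out.append(rec)
    return pd.DataFrame(out)


def heatmap_table(
    summary: pd.DataFrame,
    method: str,
    prediction_type: str = "point",
    value: str = "r2_mean",
) -> pd.DataFrame:
    """Signals x resolutions table of one summary statistic for one method."""
    sub = summary[
        (summary["method"] == method) & (summary["prediction_type"] == prediction_type)
    ]
    return sub.pivot(index="signal_name", columns="resolution", values=value)
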