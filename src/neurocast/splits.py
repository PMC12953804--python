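"""Time-series cross-validation split plans and their execution.

Three leakage-free schemes:

* ``one_step`` — expanding-window one-step-ahead evaluation: every index in
  the evaluation region (the second half of the series by default) is a
  single-point test set trained on all prior observations.  The rolled
  tests are grouped into ``n_folds`` contiguous reporting folds; the model
  order is selected once per fold on the fold's initial training range and
  the coefficients are re-estimated at every step as the window expands.
* ``blocked`` — the series is cut into sequential non-overlapping blocks;
  within each block the leading portion trains, a short gap is discarded to
  prevent adjacency leakage, and the remainder is tested by one-step-ahead
  predictions with coefficients frozen from the block's training fit.
* ``tss`` — expanding-train / fixed-test sequential splitting into
  ``n_splits + 1`` partitions.

Interval prediction (5-step horizons with Gaussian bounds) is available for
``one_step`` and ``tss`` only; the blocked scheme is restricted to point
prediction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .arima import ArimaFit, ArimaOrder, OrderGrid, fit_arima, forecast, select_order
from .resolution import ResolutionSeries, longest_segment

__all__ = [
    "Fold",
    "SplitPlan",
    "PredictionTrace",
    "one_step_folds",
    "blocked_folds",
    "tss_folds",
    "run_point_cv",
    "run_interval_cv",
]

logger = logging.getLogger(__name__)

METHODS = ("one_step", "blocked", "tss")

TRACE_COLUMNS = [
    "time_index",
    "actual",
    "predicted",
    "lower",
    "upper",
    "fold",
    "p",
    "d",
    "q",
]


@dataclass(frozen=True)
class Fold:
    """One train/test pair of half-open index ranges."""

    train: tuple[int, int]
    test: tuple[int, int]

    def __post_init__(self) -> None:
        t0, t1 = self.train
        s0, s1 = self.test
        if not (0 <= t0 < t1 <= s0 < s1):
            raise ValueError(f"fold must satisfy train < test: {self}")


@dataclass
class SplitPlan:
    method: str
    folds: list[Fold]
    n_splits: int
    n_obs: int
    gap: int = 0
    block_bounds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        prev_end = 0
        for fold in self.folds:
            if fold.test[1] > self.n_obs:
                raise ValueError("fold indices exceed series length")
            if fold.test[0] < prev_end:
                raise ValueError("test ranges overlap across folds")
            prev_end = fold.test[1]


def _group_sizes(total: int, n_groups: int) -> list[int]:
    base, extra = divmod(total, n_groups)
    return [base + (1 if i < extra else 0) for i in range(n_groups)]


def one_step_folds(
    n_obs: int, n_folds: int = 5, initial_fraction: float = 0.5
) -> SplitPlan:
    """Expanding one-step-ahead evaluation grouped into reporting folds.

    The evaluation region is ``[ceil(initial_fraction * n_obs), n_obs)``;
    each fold's train range is everything before its first test point.
    """
    start = math.ceil(initial_fraction * n_obs)
    n_tests = n_obs - start
    if n_tests < n_folds:
        raise ValueError(
            f"evaluation region of {n_tests} points cannot form {n_folds} folds"
        )
    folds = []
    pos = start
    for size in _group_sizes(n_tests, n_folds):
        folds.append(Fold(train=(0, pos), test=(pos, pos + size)))
        pos += size
    return SplitPlan(method="one_step", folds=folds, n_splits=n_folds, n_obs=n_obs)


def blocked_folds(
    n_obs: int, n_folds: int = 5, train_fraction: float = 0.7, gap: int = 2
) -> SplitPlan:
    """Sequential non-overlapping blocks with a train/gap/test layout."""
    block_size = n_obs // n_folds
    if block_size < gap + 2:
        raise ValueError("blocks too small to contain train, gap and a test point")
    folds = []
    bounds = []
    for b in range(n_folds):
        b0 = b * block_size
        b1 = n_obs if b == n_folds - 1 else (b + 1) * block_size
        size = b1 - b0
        n_train = int(math.floor(train_fraction * size))
        test_start = b0 + n_train + gap
        if n_train < 1 or test_start >= b1:
            raise ValueError(
                f"block {b} of size {size} cannot hold train, gap={gap} and a test point"
            )
        folds.append(Fold(train=(b0, b0 + n_train), test=(test_start, b1)))
        bounds.append((b0, b1))
    return SplitPlan(
        method="blocked",
        folds=folds,
        n_splits=n_folds,
        n_obs=n_obs,
        gap=gap,
        block_bounds=bounds,
    )


def tss_folds(n_obs: int, n_splits: int = 5) -> SplitPlan:
    """Expanding-train / fixed-test splits over n_splits + 1 partitions."""
    if n_obs < 2 * (n_splits + 1):
        raise ValueError("series too short for the requested number of splits")
    size = n_obs // (n_splits + 1)
    folds = []
    for k in range(1, n_splits + 1):
        test_end = (k + 1) * size if k < n_splits else n_obs  # remainder -> last fold
        folds.append(Fold(train=(0, k * size), test=(k * size, test_end)))
    return SplitPlan(method="tss", folds=folds, n_splits=n_splits, n_obs=n_obs)


@dataclass
class PredictionTrace:
    """Per-point predictions (and bounds for interval mode) from one CV run."""

    entries: pd.DataFrame
    method: str
    prediction_type: str
    horizon: int = 1
    level: float = 0.95

    def fold_metric(self, metric_fn) -> pd.Series:
        """Apply a metric(actual, predicted) per reporting fold."""
        return self.entries.groupby("fold").apply(
            lambda g: metric_fn(g["actual"].to_numpy(), g["predicted"].to_numpy()),
            include_groups=False,
        )


def _series_values(series) -> np.ndarray:
    if isinstance(series, ResolutionSeries):
        return longest_segment(series)
    return np.asarray(series, dtype=float)


def _entry(t, actual, pred, lower, upper, fold, order: Optional[ArimaOrder]):
    return {
        "time_index": int(t),
        "actual": float(actual),
        "predicted": pred,
        "lower": lower,
        "upper": upper,
        "fold": int(fold),
        "p": order.p if order else np.nan,
        "d": order.d if order else np.nan,
        "q": order.q if order else np.nan,
    }


def run_point_cv(
    series: "ResolutionSeries | Sequence[float]",
    plan: SplitPlan,
    grid: OrderGrid | None = None,
) -> PredictionTrace:
    """Execute point prediction over a split plan with per-fold order selection.

    Failures (degenerate training data, non-convergent folds) degrade to
    NaN predictions and are logged, never raised, so cohort-scale batch
    runs survive individual bad series.
    """
    values = _series_values(series)
    if plan.n_obs != len(values):
        raise ValueError(
            f"plan built for {plan.n_obs} observations, series has {len(values)}"
        )
    grid = grid or OrderGrid()
    rows: list[dict] = []
    for fold_id, fold in enumerate(plan.folds):
        train = values[fold.train[0] : fold.train[1]]
        try:
            order, fit0 = select_order(train, grid)
        except Exception as exc:
            logger.warning("fold %d: order selection failed (%s)", fold_id, exc)
            for t in range(*fold.test):
                rows.append(_entry(t, values[t], np.nan, np.nan, np.nan, fold_id, None))
            continue
        if plan.method == "one_step":
            warm: ArimaFit | None = fit0
            for t in range(*fold.test):
                try:
                    fit = fit_arima(values[:t], order, start=warm)
                    warm = fit
                    fc = forecast(fit, values[:t], 1)
                    rows.append(
                        _entry(t, values[t], float(fc.point[0]), np.nan, np.nan, fold_id, order)
                    )
                except Exception as exc:
                    logger.warning("fold %d step %d failed (%s)", fold_id, t, exc)
                    rows.append(_entry(t, values[t], np.nan, np.nan, np.nan, fold_id, None))
        else:
            # coefficients frozen from the training fit; one-step-ahead
            # predictions anchored on observed history up to each test
            # point's predecessor within the allowed information set
            info_start = fold.train[0]
            for t in range(*fold.test):
                try:
                    fc = forecast(fit0, values[info_start:t], 1)
                    rows.append(
                        _entry(t, values[t], float(fc.point[0]), np.nan, np.nan, fold_id, order)
                    )
                except Exception as exc:
                    logger.warning("fold %d step %d failed (%s)", fold_id, t, exc)
                    rows.append(_entry(t, values[t], np.nan, np.nan, np.nan, fold_id, None))
    entries = pd.DataFrame(rows, columns=TRACE_COLUMNS)
    return PredictionTrace(entries=entries, method=plan.method, prediction_type="point")


def run_interval_cv(
    series: "ResolutionSeries | Sequence[float]",
    method: str,
    horizon: int = 5,
    level: float = 0.95,
    grid: OrderGrid | None = None,
    n_splits: int = 5,
    initial_fraction: float = 0.5,
) -> PredictionTrace:
    """Interval prediction under the one_step or tss scheme.

    one_step: from the end of each expanding training window, forecast
    ``horizon`` points with intervals, then advance the window by
    ``horizon`` (non-overlapping evaluation blocks).  tss: at each split
    boundary, forecast the first ``horizon`` points of the test partition.
    """
    if method == "blocked":
        raise ValueError(
            "the blocked scheme is used for point prediction only; interval "
            "prediction is restricted to one_step and tss"
        )
    if method not in ("one_step", "tss"):
        raise ValueError(f"unknown method {method!r}")
    values = _series_values(series)
    grid = grid or OrderGrid()
    rows: list[dict] = []
    if method == "one_step":
        start = math.ceil(initial_fraction * len(values))
        if len(values) - start < horizon:
            raise ValueError("evaluation region shorter than one horizon")
        try:
            order, fit = select_order(values[:start], grid)
        except Exception as exc:
            raise RuntimeError(f"order selection failed on the initial window: {exc}")
        t = start
        block = 0
        warm: ArimaFit | None = fit
        while t + horizon <= len(values):
            try:
                fit = fit_arima(values[:t], order, start=warm)
                warm = fit
                fc = forecast(fit, values[:t], horizon, level)
                for h in range(horizon):
                    rows.append(
                        _entry(
                            t + h,
                            values[t + h],
                            float(fc.point[h]),
                            float(fc.lower[h]),
                            float(fc.upper[h]),
                            block,
                            order,
                        )
                    )
            except Exception as exc:
                logger.warning("interval window at %d failed (%s)", t, exc)
                for h in range(horizon):
                    rows.append(
                        _entry(t + h, values[t + h], np.nan, np.nan, np.nan, block, None)
                    )
            t += horizon
            block += 1
    else:
        plan = tss_folds(len(values), n_splits)
        for fold_id, fold in enumerate(plan.folds):
            train = values[fold.train[0] : fold.train[1]]
            h = min(horizon, fold.test[1] - fold.test[0])
            try:
                order, fit = select_order(train, grid)
                fc = forecast(fit, train, h, level)
                for i in range(h):
                    t = fold.test[0] + i
                    rows.append(
                        _entry(
                            t,
                            values[t],
                            float(fc.point[i]),
                            float(fc.lower[i]),
                            float(fc.upper[i]),
                            fold_id,
                            order,
                        )
                    )
            except Exception as exc:
                logger.warning("tss fold %d interval failed (%s)", fold_id, exc)
                for i in range(h):
                    t = fold.test[0] + i
                    rows.append(_entry(t, values[t], np.nan, np.nan, np.nan, fold_id, None))
    entries = pd.DataFrame(rows, columns=TRACE_COLUMNS)
    return PredictionTrace(
        entries=entries,
        method=method,
        prediction_type="interval",
        horizon=horizon,
        level=level,
    )
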