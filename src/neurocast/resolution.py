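"""Temporal resolution reduction, gap handling and stationarity diagnostics.

Minute-resolution signals are reduced to a fixed ladder of resolutions
(1 min up to 24 h) by non-overlapping averaging.  At the working resolution
the clinical gap rule is applied: interior runs of fewer than five missing
points are linearly interpolated between their flanking values, while runs
of five or more are removed, splitting the series into contiguous segments.
Differencing (with exact inversion) and from-scratch ADF / KPSS / ACF /
PACF diagnostics complete the preprocessing toolbox.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "RESOLUTION_LADDER",
    "SIGNAL_NAMES",
    "ResolutionSeries",
    "StationarityReport",
    "reduce_resolution",
    "handle_gaps",
    "longest_segment",
    "difference",
    "difference_with_state",
    "invert_difference",
    "adf_test",
    "kpss_test",
    "acf_pacf",
]

RESOLUTION_LADDER = (1, 5, 10, 15, 30, 60, 120, 180, 240, 300, 360, 720, 1440)

SIGNAL_NAMES = ("MAP", "ICP", "CPP", "PbtO2", "AMP", "PRx", "PAx", "RAC", "RAP")

# a run of this many or more consecutive missing points is removed rather
# than interpolated (runs of exactly five fall on the removal side)
GAP_REMOVAL_THRESHOLD = 5


@dataclass
class ResolutionSeries:
    """One signal at one working resolution.

    ``values`` holds NaN at invalid positions; ``segment_bounds`` lists the
    half-open index ranges of contiguous valid data (populated after
    :func:`handle_gaps`; on construction it reflects the current valid runs).
    """

    signal_name: str
    resolution: int
    values: np.ndarray
    valid: np.ndarray
    segment_bounds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.resolution not in RESOLUTION_LADDER:
            raise ValueError(
                f"resolution {self.resolution} not in the ladder {RESOLUTION_LADDER}"
            )
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if len(self.values) != len(self.valid):
            raise ValueError("values and valid must align")
        if not self.segment_bounds:
            self.segment_bounds = _valid_runs(self.valid)


def _valid_runs(valid: np.ndarray) -> list[tuple[int, int]]:
    runs: list[tuple[int, int]] = []
    n = len(valid)
    i = 0
    while i < n:
        if valid[i]:
            j = i
            while j < n and valid[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def reduce_resolution(
    minute_values: Sequence[float], resolution: int, signal_name: str = ""
) -> ResolutionSeries:
    """Non-overlapping averaging of a minute series down the resolution ladder.

    Each output point is the mean of the non-missing minutes in its window
    and is valid iff at least 50% of the window's minutes are present.  A
    trailing incomplete window is dropped; resolution 1 is the identity on
    valid minutes.
    """
    if resolution not in RESOLUTION_LADDER:
        raise ValueError(
            f"resolution {resolution} not in the ladder {RESOLUTION_LADDER}"
        )
    x = np.asarray(minute_values, dtype=float)
    n_windows = len(x) // resolution
    x = x[: n_windows * resolution].reshape(n_windows, resolution)
    present = np.isfinite(x)
    counts = present.sum(axis=1)
    valid = counts * 2 >= resolution
    sums = np.where(present, x, 0.0).sum(axis=1)
    values = np.full(n_windows, np.nan)
    ok = counts > 0
    values[ok] = sums[ok] / counts[ok]
    values[~valid] = np.nan
    return ResolutionSeries(signal_name, resolution, values, valid)


def handle_gaps(series: ResolutionSeries) -> ResolutionSeries:
    """Apply the clinical missing-data rule at the working resolution.

    Interior missing runs of 1-4 points are filled by linear interpolation
    between the flanking valid values; runs of 5 or more are removed,
    splitting the series into segments.  Leading and trailing missing runs
    have no flank to interpolate from and are trimmed.
    """
    values = series.values.copy()
    valid = series.valid.copy()
    n = len(values)
    segments: list[tuple[int, int]] = []
    if not valid.any():
        return replace(series, values=values, valid=valid, segment_bounds=[])

    first = int(np.argmax(valid))
    last = n - int(np.argmax(valid[::-1]))  # one past last valid
    seg_start = first
    i = first
    while i < last:
        if valid[i]:
            i += 1
            continue
        j = i
        while j < last and not valid[j]:
            j += 1
        run = j - i
        if run < GAP_REMOVAL_THRESHOLD:
            left, right = values[i - 1], values[j]
            frac = np.arange(1, run + 1) / (run + 1)
            values[i:j] = left + frac * (right - left)
            valid[i:j] = True
        else:
            segments.append((seg_start, i))
            seg_start = j
        i = j
    segments.append((seg_start, last))
    segments = [(a, b) for a, b in segments if b > a]
    return replace(series, values=values, valid=valid, segment_bounds=segments)


def longest_segment(series: ResolutionSeries) -> np.ndarray:
    """Values of the longest contiguous valid segment (modeling input)."""
    if not series.segment_bounds:
        return np.empty(0)
    a, b = max(series.segment_bounds, key=lambda ab: ab[1] - ab[0])
    return series.values[a:b]


# ---------------------------------------------------------------------------
# differencing


def difference(values: Sequence[float], d: int) -> np.ndarray:
    """Iterated first differences applied d times (d in {0, 1, 2})."""
    if d not in (0, 1, 2):
        raise ValueError("d must be 0, 1 or 2")
    x = np.asarray(values, dtype=float)
    if len(x) <= d:
        raise ValueError("series too short to difference")
    return np.diff(x, n=d) if d else x.copy()


def difference_with_state(values: Sequence[float], d: int) -> tuple[np.ndarray, list[float]]:
    """Difference and keep the initial value of each level for exact inversion."""
    x = np.asarray(values, dtype=float)
    if d not in (0, 1, 2):
        raise ValueError("d must be 0, 1 or 2")
    if len(x) <= d:
        raise ValueError("series too short to difference")
    initials: list[float] = []
    for _ in range(d):
        initials.append(float(x[0]))
        x = np.diff(x)
    return x, initials


def invert_difference(diffed: Sequence[float], initials: Sequence[float]) -> np.ndarray:
    """Exact inverse of :func:`difference_with_state`."""
    x = np.asarray(diffed, dtype=float)
    for init in reversed(list(initials)):
        x = np.concatenate([[init], init + np.cumsum(x)])
    return x


# ---------------------------------------------------------------------------
# stationarity diagnostics


@dataclass(frozen=True)
class StationarityReport:
    """ADF and/or KPSS results at the 5% level.

    ``adf_reject_unit_root`` True means the ADF t-ratio fell below its
    critical value (evidence of stationarity); ``kpss_reject_stationarity``
    True means the KPSS LM statistic exceeded 0.463 (evidence against level
    stationarity).
    """

    n_obs: int
    adf_statistic: Optional[float] = None
    adf_reject_unit_root: Optional[bool] = None
    kpss_statistic: Optional[float] = None
    kpss_reject_stationarity: Optional[bool] = None
    lags_used: Optional[int] = None


# MacKinnon (2010) response-surface coefficients for the constant-only ADF
# tau distribution: cv = b0 + b1/T + b2/T^2 + b3/T^3
_ADF_CV_5PCT = (-2.86154, -2.8903, -4.234, -40.040)

_KPSS_CV_5PCT = 0.463  # level-stationary variant


def adf_test(values: Sequence[float], max_lag: int | None = None) -> StationarityReport:
    """Augmented Dickey-Fuller test (constant, no trend), lag order by AIC.

    Fits ``dy_t = a + g*y_{t-1} + sum_i d_i dy_{t-i} + e`` by least squares
    on the common sample implied by ``max_lag`` for every candidate lag
    order, picks the AIC-minimizing order, and compares the t-ratio of g
    against the MacKinnon 5% critical value.
    """
    y = np.asarray(values, dtype=float)
    n = len(y)
    if n < 20:
        raise ValueError("need at least 20 observations")
    if np.ptp(y) == 0:
        raise ValueError("constant series has no unit-root structure to test")
    if max_lag is None:
        max_lag = min(int(np.ceil(12.0 * (n / 100.0) ** 0.25)), n // 2 - 5)
    max_lag = max(int(max_lag), 0)
    dy = np.diff(y)
    # rows t = max_lag .. len(dy)-1 (common across candidate lag orders)
    rows = np.arange(max_lag, len(dy))
    n_eff = len(rows)
    if n_eff < max_lag + 5:
        raise ValueError("series too short for the requested max_lag")
    target = dy[rows]
    lagged_level = y[rows]  # y_{t-1} relative to dy_t
    best = None
    for k in range(max_lag + 1):
        cols = [np.ones(n_eff), lagged_level]
        for i in range(1, k + 1):
            cols.append(dy[rows - i])
        X = np.column_stack(cols)
        beta, *_ = np.linalg.lstsq(X, target, rcond=None)
        resid = target - X @ beta
        ssr = float(resid @ resid)
        aic = n_eff * np.log(max(ssr / n_eff, 1e-300)) + 2.0 * (k + 2)
        if best is None or aic < best[0]:
            best = (aic, k)
    _, k_best = best
    # final regression re-estimated on the full sample the chosen lag allows
    rows = np.arange(k_best, len(dy))
    n_eff = len(rows)
    cols = [np.ones(n_eff), y[rows]]
    for i in range(1, k_best + 1):
        cols.append(dy[rows - i])
    X = np.column_stack(cols)
    target = dy[rows]
    beta, *_ = np.linalg.lstsq(X, target, rcond=None)
    resid = target - X @ beta
    ssr = float(resid @ resid)
    dof = n_eff - X.shape[1]
    s2 = ssr / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    se_gamma = np.sqrt(s2 * xtx_inv[1, 1])
    stat = float(beta[1] / se_gamma)
    b0, b1, b2, b3 = _ADF_CV_5PCT
    cv = b0 + b1 / n_eff + b2 / n_eff**2 + b3 / n_eff**3
    return StationarityReport(
        n_obs=n_eff,
        adf_statistic=stat,
        adf_reject_unit_root=bool(stat < cv),
        lags_used=k_best,
    )


def kpss_test(values: Sequence[float]) -> StationarityReport:
    """KPSS level-stationarity test with Bartlett-kernel long-run variance.

    Bandwidth ``l = floor(4 * (n/100)^(1/4))``; the LM statistic is compared
    against the 5% critical value 0.463.
    """
    y = np.asarray(values, dtype=float)
    n = len(y)
    if n < 20:
        raise ValueError("need at least 20 observations")
    if np.ptp(y) == 0:
        raise ValueError("constant series has zero variance")
    e = y - y.mean()
    s = np.cumsum(e)
    lag = int(np.floor(4.0 * (n / 100.0) ** 0.25))
    gamma0 = float(e @ e) / n
    lrv = gamma0
    for j in range(1, lag + 1):
        gamma_j = float(e[:-j] @ e[j:]) / n
        lrv += 2.0 * (1.0 - j / (lag + 1.0)) * gamma_j
    stat = float((s @ s) / (n**2 * lrv))
    return StationarityReport(
        n_obs=n,
        kpss_statistic=stat,
        kpss_reject_stationarity=bool(stat > _KPSS_CV_5PCT),
        lags_used=lag,
    )


def acf_pacf(
    values: Sequence[float], n_lags: int
) -> tuple[np.ndarray, np.ndarray, float]:
    """Sample ACF and PACF with the +-1.96/sqrt(n) white-noise band.

    ACF uses the biased (1/n) autocovariance estimator; PACF follows the
    Durbin-Levinson recursion.  Both arrays have length ``n_lags + 1`` with
    lag 0 fixed at 1.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n <= n_lags + 1:
        raise ValueError("series too short for the requested number of lags")
    xc = x - x.mean()
    var = float(xc @ xc) / n
    if var == 0:
        raise ValueError("zero-variance series")
    acf = np.empty(n_lags + 1)
    acf[0] = 1.0
    for k in range(1, n_lags + 1):
        acf[k] = (float(xc[:-k] @ xc[k:]) / n) / var

    pacf = np.empty(n_lags + 1)
    pacf[0] = 1.0
    phi_prev = np.empty(0)
    for k in range(1, n_lags + 1):
        if k == 1:
            phi_k = np.array([acf[1]])
        else:
            num = acf[k] - phi_prev @ acf[1:k][::-1]
            den = 1.0 - phi_prev @ acf[1:k]
            a_kk = num / den if den != 0 else 0.0
            phi_k = np.empty(k)
            phi_k[: k - 1] = phi_prev - a_kk * phi_prev[::-1]
            phi_k[k - 1] = a_kk
        pacf[k] = phi_k[-1]
        phi_prev = phi_k
    band = 1.96 / np.sqrt(n)
    return acf, pacf, band
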