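"""ARIMA(p, d, q) estimation, AIC order selection and forecasting.

Estimation maximizes the conditional-sum-of-squares (CSS) Gaussian
likelihood of Eq-style ARMA residuals on the d-times-differenced series:

    w_t = c + sum_{i<=p} phi_i w_{t-i} + e_t + sum_{j<=q} theta_j e_{t-j}

with residuals zero-initialized for t <= max(p, q).  Stationarity of the AR
polynomial and invertibility of the MA polynomial are enforced by
optimizing over partial autocorrelations mapped through tanh (the
Durbin-Levinson / Monahan transform), so every optimizer iterate is
admissible.  The innovation variance is concentrated out analytically.

The constant c is estimated when d = 0 and fixed at 0 when d >= 1 (a
constant under differencing would imply a deterministic polynomial trend).

Order selection scans a (p, d, q) grid — by default p in 1..10, d in 0..2,
q in 0..10 — and keeps the converged fit with minimum AIC = 2k - 2 logL,
k = p + q + 2.  Forecasting propagates the conditional-expectation
recursion on the differenced scale, integrates d times, and builds Gaussian
prediction intervals from psi (MA-infinity) weights cumulated to the
original scale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import optimize
from scipy import signal as spsignal
from scipy import stats

from .resolution import difference_with_state

__all__ = [
    "ArimaOrder",
    "ArimaFit",
    "Forecast",
    "OrderGrid",
    "css_loglik",
    "fit_arima",
    "select_order",
    "psi_weights",
    "forecast",
    "residuals",
]

logger = logging.getLogger(__name__)

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class ArimaOrder:
    """Model order; bounds match the selection grid (note the p >= 1 floor)."""

    p: int
    d: int
    q: int

    def __post_init__(self) -> None:
        if not 1 <= self.p <= 10:
            raise ValueError("p must be in [1, 10]")
        if not 0 <= self.d <= 2:
            raise ValueError("d must be in [0, 2]")
        if not 0 <= self.q <= 10:
            raise ValueError("q must be in [0, 10]")


@dataclass
class ArimaFit:
    """Estimated ARIMA model.

    ``aic = 2k - 2 log_likelihood`` with ``k = p + q + 2`` (constant and
    innovation variance counted).
    """

    order: ArimaOrder
    constant: float
    ar: np.ndarray
    ma: np.ndarray
    innovation_variance: float
    log_likelihood: float
    aic: float
    converged: bool
    n_used: int

    @property
    def sigma(self) -> float:
        return math.sqrt(self.innovation_variance)

    def to_dict(self) -> dict:
        return {
            "order": [self.order.p, self.order.d, self.order.q],
            "constant": self.constant,
            "ar": list(map(float, self.ar)),
            "ma": list(map(float, self.ma)),
            "innovation_variance": self.innovation_variance,
            "log_likelihood": self.log_likelihood,
            "aic": self.aic,
            "converged": self.converged,
            "n_used": self.n_used,
        }


@dataclass
class Forecast:
    """Point forecasts with Gaussian prediction intervals."""

    horizon: int
    point: np.ndarray
    se: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float = 0.95


@dataclass(frozen=True)
class OrderGrid:
    """Ranges scanned by :func:`select_order`."""

    p: tuple[int, ...] = tuple(range(1, 11))
    d: tuple[int, ...] = tuple(range(0, 3))
    q: tuple[int, ...] = tuple(range(0, 11))

    @classmethod
    def small(cls) -> "OrderGrid":
        """Reduced grid for quick sweeps: p 1-3, d 0-1, q 0-1."""
        return cls(p=(1, 2, 3), d=(0, 1), q=(0, 1))

    def orders(self) -> Iterable[ArimaOrder]:
        for d in self.d:
            for p in self.p:
                for q in self.q:
                    yield ArimaOrder(p, d, q)


# ---------------------------------------------------------------------------
# likelihood machinery


def _css_residuals(w: np.ndarray, c: float, ar: np.ndarray, ma: np.ndarray) -> np.ndarray:
    """ARMA residuals e_t for t = max(p, q) .. n-1 with zero-initialized e."""
    p, q = len(ar), len(ma)
    m = max(p, q)
    n = len(w)
    u = w[m:] - c
    for i in range(1, p + 1):
        u = u - ar[i - 1] * w[m - i : n - i]
    if q:
        u = spsignal.lfilter([1.0], np.r_[1.0, ma], u)
    return u


def css_loglik(
    diffed: Sequence[float],
    order: ArimaOrder | None,
    params: tuple[float, Sequence[float], Sequence[float], float],
) -> float:
    """Gaussian CSS log-likelihood of an ARMA model on a differenced series.

    ``params = (c, phi, theta, sigma2)``.  Dimension consistency with
    ``order`` is enforced when an order is given; residuals before
    ``max(p, q)`` are conditioned away.
    """
    c, phi, theta, sigma2 = params
    phi = np.asarray(phi, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    if order is not None and (len(phi) != order.p or len(theta) != order.q):
        raise ValueError("parameter lengths inconsistent with the order")
    w = np.asarray(diffed, dtype=float)
    e = _css_residuals(w, c, phi, theta)
    n_eff = len(e)
    if n_eff == 0:
        raise ValueError("no residuals; series shorter than max(p, q)")
    return float(-0.5 * n_eff * (_LOG_2PI + math.log(sigma2)) - (e @ e) / (2.0 * sigma2))


def _pacf_to_coeffs(r: np.ndarray) -> np.ndarray:
    """Map unconstrained reals to stationary AR coefficients (tanh + DL)."""
    pac = np.tanh(r)
    k = len(pac)
    a = np.zeros(k)
    for j in range(k):
        a_new = a[:j] - pac[j] * a[:j][::-1]
        a[:j] = a_new
        a[j] = pac[j]
    return a


def _coeffs_to_pacf(a: np.ndarray) -> np.ndarray:
    """Inverse of :func:`_pacf_to_coeffs`; raises for non-stationary input."""
    a = np.asarray(a, dtype=float).copy()
    k = len(a)
    pac = np.zeros(k)
    for j in range(k - 1, -1, -1):
        pac[j] = a[j]
        if abs(pac[j]) >= 1.0:
            raise ValueError("coefficients outside the stationary region")
        if j:
            head = a[:j]
            a[:j] = (head + pac[j] * head[::-1]) / (1.0 - pac[j] ** 2)
    with np.errstate(divide="ignore"):
        return np.arctanh(np.clip(pac, -1 + 1e-12, 1 - 1e-12))


def _unpack(x: np.ndarray, p: int, q: int, with_const: bool):
    idx = 0
    c = x[0] if with_const else 0.0
    idx += int(with_const)
    phi = _pacf_to_coeffs(x[idx : idx + p]) if p else np.empty(0)
    idx += p
    theta = -_pacf_to_coeffs(x[idx : idx + q]) if q else np.empty(0)
    return float(c), phi, theta


def fit_arima(
    values: Sequence[float],
    order: ArimaOrder,
    start: Optional["ArimaFit"] = None,
) -> ArimaFit:
    """Fit an ARIMA model by conditional sum of squares.

    ``start`` warm-starts the optimizer from a previous fit of the same
    order (used heavily by the rolling cross-validation loops).  A
    non-converged optimization still returns a fit, flagged
    ``converged=False``.
    """
    y = np.asarray(values, dtype=float)
    if len(y) and np.ptp(y) == 0:
        raise ValueError("zero-variance series cannot be modeled")
    p, d, q = order.p, order.d, order.q
    if len(y) <= p + q + d + 2:
        raise ValueError(
            f"series of length {len(y)} below the hard floor for order "
            f"({p},{d},{q})"
        )
    w, _ = difference_with_state(y, d)
    with_const = d == 0
    n_eff = len(w) - max(p, q)
    if n_eff < 1:
        raise ValueError("series too short after differencing")

    def neg_concentrated(x: np.ndarray) -> float:
        c, phi, theta = _unpack(x, p, q, with_const)
        e = _css_residuals(w, c, phi, theta)
        sigma2 = float(e @ e) / len(e)
        if not np.isfinite(sigma2) or sigma2 <= 0:
            return 1e12
        return 0.5 * len(e) * (_LOG_2PI + math.log(sigma2) + 1.0)

    x0 = np.zeros(int(with_const) + p + q)
    if with_const:
        x0[0] = float(np.mean(w))
    if p and len(w) > p + 2:
        # OLS autoregression as the cold start; shrunk toward the interior
        # of the stationary region so the pacf transform always succeeds
        Y = w[p:]
        X = np.column_stack(
            [np.ones(len(Y))] + [w[p - i : len(w) - i] for i in range(1, p + 1)]
        )
        try:
            beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
            for shrink in (1.0, 0.9, 0.7, 0.5):
                try:
                    r_ar = _coeffs_to_pacf(beta[1:] * shrink)
                    x0[int(with_const) : int(with_const) + p] = np.clip(r_ar, -4, 4)
                    if with_const:
                        x0[0] = float(beta[0])
                    break
                except ValueError:
                    continue
        except np.linalg.LinAlgError:
            pass
    if start is not None and start.order == order:
        try:
            xs = []
            if with_const:
                xs.append(np.array([start.constant]))
            if p:
                xs.append(_coeffs_to_pacf(np.asarray(start.ar)))
            if q:
                xs.append(_coeffs_to_pacf(-np.asarray(start.ma)))
            cand = np.concatenate(xs) if xs else np.empty(0)
            if np.all(np.isfinite(cand)):
                x0 = cand
        except ValueError:
            pass

    res = optimize.minimize(
        neg_concentrated,
        x0,
        method="L-BFGS-B",
        options={"ftol": 1e-8, "gtol": 1e-6, "maxiter": 300},
    )
    c, phi, theta = _unpack(res.x, p, q, with_const)
    e = _css_residuals(w, c, phi, theta)
    sigma2 = float(e @ e) / len(e)
    if sigma2 <= 0 or not np.isfinite(sigma2):
        sigma2 = 1e-12
    # scale the conditional likelihood to the full differenced length:
    # CSS conditions away max(p, q) initial residuals, so unscaled
    # likelihoods of different orders cover different sample sizes and AIC
    # would systematically favor the larger conditioning set
    loglik_eff = float(
        -0.5 * len(e) * (_LOG_2PI + math.log(sigma2)) - (e @ e) / (2.0 * sigma2)
    )
    loglik = loglik_eff * (len(w) / len(e))
    k = p + q + 2
    return ArimaFit(
        order=order,
        constant=c,
        ar=phi,
        ma=theta,
        innovation_variance=sigma2,
        log_likelihood=loglik,
        aic=2.0 * k - 2.0 * loglik,
        converged=bool(res.success),
        n_used=len(y),
    )


def select_order(
    values: Sequence[float], grid: OrderGrid | None = None
) -> tuple[ArimaOrder, ArimaFit]:
    """AIC grid search over (p, d, q); ties go to smaller p+q, then q, then d.

    Non-converged or failing fits are skipped (and logged); if every order
    fails, the per-order failure log is raised with the error.
    """
    grid = grid or OrderGrid()
    y = np.asarray(values, dtype=float)
    # score every candidate on the same original-time residual range:
    # zero-initialized CSS residuals cover n - d - max(p, q) points, so
    # without a common conditioning set larger orders would be compared on
    # fewer (and transient-free) residuals and AIC would overfit badly
    feasible = [o for o in grid.orders() if len(y) > o.p + o.q + o.d + 2]
    if not feasible:
        raise RuntimeError(
            f"series of length {len(y)} is below the hard floor of every "
            "order in the grid"
        )
    t0 = max(o.d + max(o.p, o.q) for o in feasible)
    best: tuple[ArimaOrder, ArimaFit, float] | None = None
    failures: dict[tuple[int, int, int], str] = {}
    for order in feasible:
        key = (order.p, order.d, order.q)
        try:
            fit = fit_arima(y, order)
        except Exception as exc:  # short series, degenerate input, ...
            failures[key] = str(exc)
            logger.debug("order %s skipped: %s", key, exc)
            continue
        if not fit.converged:
            failures[key] = "non-converged"
            logger.debug("order %s skipped: non-converged", key)
            continue
        drop = t0 - order.d - max(order.p, order.q)
        e = residuals(fit, y)[drop:]
        if len(e) < 1:
            failures[key] = "no residuals on the common conditioning set"
            continue
        sigma2_c = float(e @ e) / len(e)
        if sigma2_c <= 0:
            sigma2_c = 1e-12
        ll_c = -0.5 * len(e) * (_LOG_2PI + math.log(sigma2_c) + 1.0)
        aic_c = 2.0 * (order.p + order.q + 2) - 2.0 * ll_c
        if best is None or _better_scored(aic_c, order, best[2], best[0]):
            best = (order, fit, aic_c)
    if best is None:
        raise RuntimeError(f"all candidate orders failed: {failures}")
    return best[0], best[1]


def _better_scored(
    cand_aic: float, cand_order: ArimaOrder, inc_aic: float, inc_order: ArimaOrder
) -> bool:
    if cand_aic < inc_aic - 1e-12:
        return True
    if cand_aic > inc_aic + 1e-12:
        return False
    ck = (cand_order.p + cand_order.q, cand_order.q, cand_order.d)
    ik = (inc_order.p + inc_order.q, inc_order.q, inc_order.d)
    return ck < ik


def _better(candidate: ArimaFit, incumbent: ArimaFit) -> bool:
    if candidate.aic < incumbent.aic - 1e-12:
        return True
    if candidate.aic > incumbent.aic + 1e-12:
        return False
    ck = (candidate.order.p + candidate.order.q, candidate.order.q, candidate.order.d)
    ik = (incumbent.order.p + incumbent.order.q, incumbent.order.q, incumbent.order.d)
    return ck < ik


def psi_weights(fit: ArimaFit, horizon: int) -> np.ndarray:
    """MA-infinity weights psi_0..psi_{h-1} on the original (integrated) scale.

    On the differenced scale psi_0 = 1 and
    ``psi_j = theta_j [j <= q] + sum_{i <= min(j, p)} phi_i psi_{j-i}``;
    for d > 0 the weights are cumulatively summed d times, which converts
    innovation impacts to the undifferenced series.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    p, q = len(fit.ar), len(fit.ma)
    psi = np.zeros(horizon)
    psi[0] = 1.0
    for j in range(1, horizon):
        val = fit.ma[j - 1] if j <= q else 0.0
        for i in range(1, min(j, p) + 1):
            val += fit.ar[i - 1] * psi[j - i]
        psi[j] = val
    for _ in range(fit.order.d):
        psi = np.cumsum(psi)
    return psi


def residuals(fit: ArimaFit, history: Sequence[float]) -> np.ndarray:
    """CSS residuals of a fitted model evaluated on a series (original scale)."""
    y = np.asarray(history, dtype=float)
    w, _ = difference_with_state(y, fit.order.d)
    return _css_residuals(w, fit.constant, fit.ar, fit.ma)


def forecast(
    fit: ArimaFit, history: Sequence[float], horizon: int, level: float = 0.95
) -> Forecast:
    """h-step forecasts from the end of ``history`` with prediction intervals.

    Point forecasts follow the conditional-expectation recursion on the
    differenced scale (future innovations zero) and are integrated d times;
    ``se_h = sigma * sqrt(sum_{j<h} psi_j^2)`` with original-scale psi
    weights, and bounds use the standard-normal quantile of ``level``.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    y = np.asarray(history, dtype=float)
    p, d, q = fit.order.p, fit.order.d, fit.order.q
    if len(y) < max(p, q) + d + 1:
        raise ValueError("history too short for this model order")
    w, _ = difference_with_state(y, d)
    m = max(p, q)
    e_tail = _css_residuals(w, fit.constant, fit.ar, fit.ma)
    e_full = np.concatenate([np.zeros(m), e_tail, np.zeros(horizon)])
    w_ext = np.concatenate([w, np.zeros(horizon)])
    n = len(w)
    for h in range(horizon):
        t = n + h
        val = fit.constant
        for i in range(1, p + 1):
            val += fit.ar[i - 1] * w_ext[t - i]
        for j in range(1, q + 1):
            if t - j < n:  # only observed innovations contribute
                val += fit.ma[j - 1] * e_full[t - j]
        w_ext[t] = val
    point = w_ext[n:]
    # integrate back to the original scale from the stored history tails
    levels = [y]
    for _ in range(d):
        levels.append(np.diff(levels[-1]))
    for k in range(d - 1, -1, -1):
        point = levels[k][-1] + np.cumsum(point)
    psi = psi_weights(fit, horizon)
    se = fit.sigma * np.sqrt(np.cumsum(psi**2))
    z = stats.norm.ppf(0.5 * (1.0 + level))
    return Forecast(
        horizon=horizon,
        point=np.asarray(point, dtype=float),
        se=se,
        lower=point - z * se,
        upper=point + z * se,
        level=level,
    )
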