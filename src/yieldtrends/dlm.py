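"""Local linear trend dynamic linear model for annual yield series.

The model has observation and system equations

    Y_t = a_t + eps_t,              eps_t ~ N(0, sigma2_eps)
    Z_t = G Z_{t-1} + tau_{t-1},    tau   ~ N(0, diag(sigma2_a, sigma2_b))

with state Z_t = (a_t, b_t)', level a_t, annual growth b_t, and
transition G = [[1, 1], [0, 1]].  The three disturbance variances are
estimated by maximum likelihood via the Kalman-filter prediction-error
decomposition; smoothed states and variances come from the
fixed-interval (RTS) smoother.  Missing years perform the time update
only and contribute nothing to the likelihood.

Growth rates are reported relative to the level, g_t = b_t / a_t, with
a 90% confidence band obtained by dividing the absolute band
b_t +/- z * sqrt(var_b_t) by the level point estimate.

Initialization is an approximately diffuse proper prior: mean
(first non-missing observation, 0), covariance ``diag(init_var)`` with
``init_var = 1e7`` in squared yield units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "DLMParams",
    "TrendFit",
    "FilterResult",
    "InsufficientData",
    "EstimationError",
    "kalman_filter",
    "kalman_smooth",
    "loglikelihood",
    "fit_dlm",
    "relative_growth",
]

Z90 = 1.6449  # two-sided 90% normal quantile

DEFAULT_INIT_VAR = 1e7
MIN_OBS_DEFAULT = 30

_LOG2PI = math.log(2.0 * math.pi)


class InsufficientData(ValueError):
    """Fewer non-missing observations than the estimation rule allows."""


class EstimationError(RuntimeError):
    """The variance optimizer failed to converge from every start."""


@dataclass(frozen=True)
class DLMParams:
    """Disturbance variances of the local linear trend model."""

    sigma2_eps: float
    sigma2_a: float
    sigma2_b: float

    def __post_init__(self) -> None:
        v = (self.sigma2_eps, self.sigma2_a, self.sigma2_b)
        if any(x < 0 for x in v):
            raise ValueError("variances must be non-negative")
        if all(x == 0 for x in v):
            raise ValueError("at least one variance must be positive")


@dataclass
class FilterResult:
    years: np.ndarray
    # predicted (one-step-ahead) and filtered moments per year
    pred_mean: np.ndarray  # (T, 2)
    pred_cov: np.ndarray  # (T, 2, 2)
    filt_mean: np.ndarray  # (T, 2)
    filt_cov: np.ndarray  # (T, 2, 2)
    loglik: float
    n_obs: int


@dataclass
class TrendFit:
    """Smoothed trend: level a_t, growth b_t, variances, relative growth."""

    years: np.ndarray
    a: np.ndarray
    var_a: np.ndarray
    b: np.ndarray
    var_b: np.ndarray
    g: np.ndarray
    g_lo: np.ndarray
    g_hi: np.ndarray
    n_obs: int
    loglik: float
    params: DLMParams

    def __len__(self) -> int:
        return len(self.years)


def _init_state(y: np.ndarray, init_var: float) -> tuple[np.ndarray, np.ndarray]:
    obs = np.flatnonzero(~np.isnan(y))
    if obs.size == 0:
        raise InsufficientData("series is entirely missing")
    m0 = np.array([y[obs[0]], 0.0])
    P0 = np.diag([init_var, init_var])
    return m0, P0


def loglikelihood(
    y: np.ndarray, params: DLMParams, init_var: float = DEFAULT_INIT_VAR
) -> float:
    """Prediction-error log-likelihood, scalar recursion (fast path).

    The prior acts as the predicted distribution of the first year's
    state.  Identical in value to :func:`kalman_filter`'s ``loglik``.
    """
    se, qa, qb = params.sigma2_eps, params.sigma2_a, params.sigma2_b
    obs = np.flatnonzero(~np.isnan(y))
    a = float(y[obs[0]])
    b = 0.0
    p11 = p22 = init_var
    p12 = 0.0
    ll = 0.0
    first = True
    for t in range(len(y)):
        if not first:
            # time update: Z_t = G Z_{t-1} + tau
            a += b
            p11 += 2.0 * p12 + p22 + qa
            p12 += p22
            p22 += qb
        first = False
        yt = y[t]
        if yt == yt:  # not NaN
            s = p11 + se
            v = yt - a
            ll -= 0.5 * (_LOG2PI + math.log(s) + v * v / s)
            k1 = p11 / s
            k2 = p12 / s
            a += k1 * v
            b += k2 * v
            p22 -= k2 * p12
            p12 -= k1 * p12
            p11 -= k1 * p11
    return ll


def kalman_filter(
    y: np.ndarray, params: DLMParams, init_var: float = DEFAULT_INIT_VAR,
    years: np.ndarray | None = None,
) -> FilterResult:
    """Forward pass storing predicted and filtered moments per year."""
    y = np.asarray(y, dtype=float)
    T = len(y)
    if T < 2:
        raise ValueError("series must have length >= 2")
    if years is None:
        years = np.arange(T)
    m, P = _init_state(y, init_var)
    G = np.array([[1.0, 1.0], [0.0, 1.0]])
    Q = np.diag([params.sigma2_a, params.sigma2_b])
    pred_mean = np.empty((T, 2))
    pred_cov = np.empty((T, 2, 2))
    filt_mean = np.empty((T, 2))
    filt_cov = np.empty((T, 2, 2))
    ll = 0.0
    n_obs = 0
    for t in range(T):
        if t > 0:
            m = G @ m
            P = G @ P @ G.T + Q
        pred_mean[t] = m
        pred_cov[t] = P
        if not np.isnan(y[t]):
            s = P[0, 0] + params.sigma2_eps
            v = y[t] - m[0]
            ll -= 0.5 * (_LOG2PI + math.log(s) + v * v / s)
            n_obs += 1
            K = P[:, 0] / s
            m = m + K * v
            P = P - np.outer(K, P[0, :])
            P = 0.5 * (P + P.T)
        filt_mean[t] = m
        filt_cov[t] = P
    return FilterResult(
        years=np.asarray(years), pred_mean=pred_mean, pred_cov=pred_cov,
        filt_mean=filt_mean, filt_cov=filt_cov, loglik=ll, n_obs=n_obs,
    )


def kalman_smooth(
    y: np.ndarray, params: DLMParams, init_var: float = DEFAULT_INIT_VAR,
    years: np.ndarray | None = None, level: float = 0.90,
) -> TrendFit:
    """Fixed-interval (RTS) smoother; returns the full :class:`TrendFit`.

    Smoothed states are produced for every year, including missing
    ones.
    """
    y = np.asarray(y, dtype=float)
    fr = kalman_filter(y, params, init_var, years)
    T = len(y)
    G = np.array([[1.0, 1.0], [0.0, 1.0]])
    sm = fr.filt_mean.copy()
    sP = fr.filt_cov.copy()
    for t in range(T - 2, -1, -1):
        Pp = fr.pred_cov[t + 1]
        C = fr.filt_cov[t] @ G.T @ np.linalg.inv(Pp)
        sm[t] = fr.filt_mean[t] + C @ (sm[t + 1] - fr.pred_mean[t + 1])
        sP[t] = fr.filt_cov[t] + C @ (sP[t + 1] - Pp) @ C.T
        sP[t] = 0.5 * (sP[t] + sP[t].T)
    a = sm[:, 0]
    b = sm[:, 1]
    var_a = np.maximum(sP[:, 0, 0], 0.0)
    var_b = np.maximum(sP[:, 1, 1], 0.0)
    g, lo, hi = relative_growth(a, b, var_b, level=level)
    return TrendFit(
        years=fr.years, a=a, var_a=var_a, b=b, var_b=var_b,
        g=g, g_lo=lo, g_hi=hi, n_obs=fr.n_obs, loglik=fr.loglik, params=params,
    )


def relative_growth(
    a: np.ndarray, b: np.ndarray, var_b: np.ndarray, level: float = 0.90
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Relative growth g_t = b_t / a_t with its confidence band.

    The band is the absolute-growth normal band divided by the level
    point estimate; uncertainty in a_t is ignored.  Years with a
    non-positive level have an undefined rate and come back as NaN.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    var_b = np.asarray(var_b, float)
    z = Z90 if abs(level - 0.90) < 1e-12 else float(stats.norm.ppf(0.5 + level / 2))
    half = z * np.sqrt(var_b)
    bad = a <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(bad, np.nan, b / a)
        lo = np.where(bad, np.nan, (b - half) / a)
        hi = np.where(bad, np.nan, (b + half) / a)
    return g, lo, hi


# ---------------------------------------------------------------------------
# maximum-likelihood estimation


def _start_points(y: np.ndarray) -> list[np.ndarray]:
    """Deterministic optimizer starts spanning signal/noise ratios.

    The total sample variance of year-to-year differences sets the
    scale; five starts allocate it between observation noise and state
    noise at ratios 1e-2 .. 1e2.
    """
    obs = y[~np.isnan(y)]
    d = np.diff(obs)
    scale = float(np.var(d)) / 2.0 if d.size > 1 else max(float(np.var(obs)), 1e-4)
    scale = max(scale, 1e-8)
    starts = []
    for r in (1e-2, 1e-1, 1.0, 1e1, 1e2):
        se = scale / (1.0 + r)
        sq = scale * r / (1.0 + r)
        starts.append(np.log([max(se, 1e-12), max(sq / 2, 1e-12),
                              max(sq / 20, 1e-12)]))
    return starts


def fit_dlm(
    y: np.ndarray,
    years: np.ndarray | None = None,
    min_obs: int = MIN_OBS_DEFAULT,
    init_var: float = DEFAULT_INIT_VAR,
    level: float = 0.90,
) -> tuple[DLMParams, TrendFit]:
    """Estimate the three variances by ML and return the smoothed fit.

    Series with fewer than ``min_obs`` non-missing observations are
    refused with :class:`InsufficientData` (callers record them as not
    estimated).  The optimizer maximizes over log-variances
    (unconstrained) with L-BFGS-B from five deterministic starts and
    keeps the best likelihood.
    """
    y = np.asarray(y, dtype=float)
    n_obs = int(np.sum(~np.isnan(y)))
    if n_obs < min_obs:
        raise InsufficientData(
            f"{n_obs} observations < required minimum {min_obs}"
        )

    def neg_loglik(theta: np.ndarray) -> float:
        se, qa, qb = np.exp(np.clip(theta, -40.0, 40.0))
        return -loglikelihood(y, DLMParams(se, qa, qb), init_var)

    best = None
    for x0 in _start_points(y):
        res = optimize.minimize(
            neg_loglik, x0, method="L-BFGS-B",
            options={"ftol": 1e-10, "gtol": 1e-8, "maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise EstimationError("variance optimization failed from every start")
    se, qa, qb = np.exp(np.clip(best.x, -40.0, 40.0))
    params = DLMParams(float(se), float(qa), float(qb))
    fit = kalman_smooth(y, params, init_var, years, level=level)
    return params, fit
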