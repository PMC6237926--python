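"""Inter-annual yield variability analytics.

Variability is studied on *residuals*, the values left after
subtracting the smoothed trend level from the observed yields.  The
central statistic is the decadal coefficient of variation: the decade
standard deviation of the residuals over the decade mean of the raw
yields.  Mean-variance scaling across decades and departments follows a
Taylor power law, sd = alpha * mean**beta, fitted by OLS on log10
scales.  Cross-crop synchrony of good and bad years is measured by
Pearson correlation of nationally aggregated residual series (mean and
5%/95% cross-department percentiles).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dlm import TrendFit
from .panel import YieldPanel

__all__ = [
    "ResidualSeries",
    "DecadeStat",
    "TaylorFit",
    "residuals",
    "decadal_cv",
    "cv_category",
    "taylor_power_fit",
    "disturbed_decades",
    "residual_skewness",
    "quantile_trends",
    "cross_crop_residual_correlation",
]

#: CV category edges (fractions): 1 = CV<10%, 2 = 10-20%, 3 = 20-30%,
#: 4 = 30-40%, 5 = >40%.  The 20% boundary separates low (1-2) from
#: moderate-to-high (3-5) variability.
DEFAULT_CV_EDGES = (0.10, 0.20, 0.30, 0.40)

QUANTILES = (0.05, 0.10, 0.25, 0.50, 0.75, 0.90, 0.95)


@dataclass
class ResidualSeries:
    """Trend residuals r_t = Y_t - a_t at observed years only."""

    years: np.ndarray
    values: np.ndarray

    def __len__(self) -> int:
        return len(self.years)


@dataclass(frozen=True)
class DecadeStat:
    crop: str
    department_id: str
    decade: int  # start year of the decade
    mean_yield: float
    sd_resid: float
    cv: float
    cv_category: int
    n: int


@dataclass(frozen=True)
class TaylorFit:
    slope: float
    intercept: float  # log10(alpha)
    r2: float
    n: int


def residuals(years: np.ndarray, y: np.ndarray, fit: TrendFit) -> ResidualSeries:
    """Observed minus smoothed level, at non-missing years only."""
    years = np.asarray(years)
    y = np.asarray(y, float)
    if len(years) != len(y):
        raise ValueError("years and values differ in length")
    idx = {int(yr): i for i, yr in enumerate(fit.years)}
    out_years, out_vals = [], []
    for yr, val in zip(years, y):
        if np.isnan(val):
            continue
        i = idx.get(int(yr))
        if i is None:
            raise ValueError(f"year {yr} not covered by the trend fit")
        out_years.append(int(yr))
        out_vals.append(val - fit.a[i])
    return ResidualSeries(np.array(out_years), np.array(out_vals))


def cv_category(cv: float, edges: Sequence[float] = DEFAULT_CV_EDGES) -> int:
    """Map a CV to its category 1..len(edges)+1 (upper edges inclusive)."""
    if cv < 0:
        raise ValueError("CV must be non-negative")
    for i, e in enumerate(edges):
        if cv <= e:
            return i + 1
    return len(edges) + 1


def _decade_edges(year_range: tuple[int, int]) -> list[tuple[int, int]]:
    start = (year_range[0] // 10) * 10
    out = []
    while start <= year_range[1]:
        out.append((start, min(start + 9, year_range[1])))
        start += 10
    return out


def decadal_cv(
    crop: str,
    department_id: str,
    resid: ResidualSeries,
    years: np.ndarray,
    y: np.ndarray,
    year_range: tuple[int, int] = (1900, 2016),
    min_obs: int = 5,
    edges: Sequence[float] = DEFAULT_CV_EDGES,
) -> list[DecadeStat]:
    """Per-decade CV = SD(residuals) / mean(raw yields) for one series.

    Calendar decades (1900-1909, ..., last truncated); decades with
    fewer than ``min_obs`` observations are suppressed.  A decade with a
    non-positive mean yield is an error (CV undefined).
    """
    years = np.asarray(years)
    y = np.asarray(y, float)
    rmap = dict(zip(resid.years.tolist(), resid.values.tolist()))
    out = []
    for d0, d1 in _decade_edges(year_range):
        sel = (years >= d0) & (years <= d1) & ~np.isnan(y)
        yrs = years[sel]
        if len(yrs) < min_obs:
            continue
        rv = np.array([rmap[int(t)] for t in yrs if int(t) in rmap])
        if len(rv) < min_obs:
            continue
        mean = float(np.mean(y[sel]))
        if mean <= 0:
            raise ValueError(f"decade {d0}: non-positive mean yield, CV undefined")
        sd = float(np.std(rv, ddof=1))
        cv = sd / mean
        out.append(
            DecadeStat(crop, department_id, d0, mean, sd, cv,
                       cv_category(cv, edges), int(len(rv)))
        )
    return out


def disturbed_decades(
    periods: Sequence[tuple[int, int, float]] = ((1914, 1918, 0.7),
                                                (1939, 1945, 0.7)),
    recovery_years: int = 3,
) -> set[int]:
    """Decade start years touched by a war period or its recovery tail.

    Wartime level shifts are systematic trend disturbances, not
    inter-annual noise; the trend model tracks them imperfectly, so
    residual SDs in these decades conflate tracking error with
    sampling variability.  Used to exclude such decades from the
    mean-variance power-law fit.
    """
    out: set[int] = set()
    for w0, w1, _ in periods:
        for yr in range(w0, w1 + recovery_years + 1):
            out.add((yr // 10) * 10)
    return out


def taylor_power_fit(
    decade_stats: Sequence[DecadeStat],
    exclude_decades: Sequence[int] = (),
) -> TaylorFit:
    """OLS of log10(sd_resid) on log10(mean_yield) across decade points.

    The slope is the Taylor exponent beta; slope < 1 means absolute
    variability grows slower than the mean, so the CV declines as
    yields rise.  Decades listed in ``exclude_decades`` (typically
    war-disturbed ones, see :func:`disturbed_decades`) are left out of
    the fit.
    """
    excl = set(exclude_decades)
    pts = [(s.mean_yield, s.sd_resid) for s in decade_stats
           if s.mean_yield > 0 and s.sd_resid > 0 and s.decade not in excl]
    if len(pts) < 3:
        raise ValueError("need at least 3 usable (mean, sd) points")
    x = np.log10([p[0] for p in pts])
    yv = np.log10([p[1] for p in pts])
    if np.ptp(x) == 0:
        raise ValueError("degenerate fit: all means equal")
    res = stats.linregress(x, yv)
    return TaylorFit(float(res.slope), float(res.intercept),
                     float(res.rvalue**2), len(pts))


def residual_skewness(values: Sequence[float]) -> float:
    """Adjusted Fisher-Pearson sample skewness of pooled residuals."""
    v = np.asarray(values, float)
    v = v[~np.isnan(v)]
    if len(v) < 3:
        raise ValueError("need at least 3 residuals")
    if np.std(v) == 0:
        raise ValueError("zero variance: skewness undefined")
    return float(stats.skew(v, bias=False))


def quantile_trends(
    panel: YieldPanel, crop: str, season_type: str = "aggregate",
    quantiles: Sequence[float] = QUANTILES,
) -> pd.DataFrame:
    """Per-year cross-department min/max/quantiles of yields.

    Empirical quantiles use linear interpolation between order
    statistics.  Years with a single reporting department are kept but
    flagged (``degenerate``) since all quantiles collapse to the one
    value.
    """
    df = panel.df
    m = (df["crop"] == crop) & (df["season_type"] == season_type)
    sub = df.loc[m & df["yield_t_ha"].notna()]
    rows = []
    for year, g in sub.groupby("year"):
        v = g["yield_t_ha"].to_numpy()
        row = {"year": int(year), "n_depts": len(v),
               "min": float(v.min()), "max": float(v.max()),
               "degenerate": len(v) < 2}
        for q in quantiles:
            row[f"q{int(round(q * 100)):02d}"] = float(
                np.quantile(v, q, method="linear")
            )
        rows.append(row)
    return pd.DataFrame(rows).sort_values("year").reset_index(drop=True)


def cross_crop_residual_correlation(
    series: Mapping[str, ResidualSeries], min_years: int = 10
) -> pd.DataFrame:
    """Pearson correlation of national residual series for crop pairs.

    ``series`` maps crop (or "crop|q05"-style labels) to residual
    series; each pair is correlated on its maximal common span.  Pairs
    with fewer than ``min_years`` common years are marked
    not-assessable (r and p NaN).  Output is a long symmetric table
    with unit diagonal and a ``significant`` mask at p < 0.05.
    """
    names = sorted(series)
    rows = []
    for a in names:
        rows.append((a, a, 1.0, 0.0, len(series[a]), True))
    for a, b in combinations(names, 2):
        sa, sb = series[a], series[b]
        common, ia, ib = np.intersect1d(sa.years, sb.years, return_indices=True)
        if len(common) < min_years:
            r = p = np.nan
            sig = False
        else:
            r, p = stats.pearsonr(sa.values[ia], sb.values[ib])
            sig = bool(p < 0.05)
        rows.append((a, b, float(r), float(p), int(len(common)), sig))
        rows.append((b, a, float(r), float(p), int(len(common)), sig))
    return pd.DataFrame(
        rows, columns=["crop_a", "crop_b", "r", "p", "n_years", "significant"]
    ).sort_values(["crop_a", "crop_b"]).reset_index(drop=True)
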