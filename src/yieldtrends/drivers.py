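"""Correlation of yield series with auxiliary driver series.

Drivers are department-level annual totals — mineral fertilizer
applications (N, P2O5, K2O, tonnes) or a national irrigated-area
series — and are *not* crop-specific, which limits how much can be read
into per-crop correlations.  Two modes are provided: ``raw`` correlates
the level series on their common span (trend-dominated, so high r means
shared long-run movement), while ``detrended`` first removes a
smoothed trend from each series and correlates the residuals
(inter-annual co-variation, robust to spurious shared trends).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats

from .dlm import fit_dlm

__all__ = [
    "DRIVER_COLUMNS",
    "DriverSeries",
    "driver_correlation",
    "summarize_driver_correlations",
]

DRIVER_COLUMNS = ("department_id", "driver", "year", "value")

DEFAULT_FERTILIZER_SPAN = (1946, 2013)


@dataclass
class DriverSeries:
    """One department's annual series for one driver."""

    department_id: str  # or "national"
    driver: str  # e.g. N, P2O5, K2O, irrigated_area
    years: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, int)
        self.values = np.asarray(self.values, float)
        if len(self.years) != len(self.values):
            raise ValueError("years and values differ in length")
        if len(np.unique(self.years)) != len(self.years):
            raise ValueError("duplicate years in driver series")
        if np.any(self.values[~np.isnan(self.values)] < 0):
            raise ValueError("driver values must be non-negative")


def _detrend(years: np.ndarray, values: np.ndarray, min_obs: int) -> np.ndarray:
    _, fit = fit_dlm(values, years=years, min_obs=min_obs)
    out = values - fit.a
    return out


def driver_correlation(
    yield_years: np.ndarray,
    yield_values: np.ndarray,
    driver: DriverSeries,
    mode: str = "raw",
    min_years: int = 10,
) -> dict:
    """Pearson correlation between a yield series and a driver series.

    ``raw`` correlates levels; ``detrended`` removes a smoothed trend
    from each series first and correlates the residuals.  Returns a
    dict with r, p, n_years and the mode; raises ``ValueError`` when
    the common span is shorter than ``min_years``.
    """
    if mode not in ("raw", "detrended"):
        raise ValueError(f"unknown mode {mode!r}")
    yy = np.asarray(yield_years, int)
    yv = np.asarray(yield_values, float)
    ok_y = ~np.isnan(yv)
    ok_d = ~np.isnan(driver.values)
    common, ia, ib = np.intersect1d(
        yy[ok_y], driver.years[ok_d], return_indices=True
    )
    if len(common) < min_years:
        raise ValueError(
            f"only {len(common)} common years (< {min_years}): not assessable"
        )
    a = yv[ok_y][ia]
    b = driver.values[ok_d][ib]
    if mode == "detrended":
        a = _detrend(common, a, min_obs=min_years)
        b = _detrend(common, b, min_obs=min_years)
    r, p = stats.pearsonr(a, b)
    return {"r": float(r), "p": float(p), "n_years": int(len(common)),
            "mode": mode}


def summarize_driver_correlations(
    per_department: Mapping[str, dict], crop: str, driver: str
) -> dict:
    """Unweighted mean r across departments and share significant.

    ``per_department`` maps department IDs to :func:`driver_correlation`
    results (one mode).
    """
    if not per_department:
        raise ValueError("no department correlations to summarize")
    rs = [d["r"] for d in per_department.values()]
    sig = [d["p"] < 0.05 for d in per_department.values()]
    return {
        "crop": crop,
        "driver": driver,
        "mean_r": float(np.mean(rs)),
        "share_significant": float(np.mean(sig)),
        "n_departments": len(rs),
    }
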