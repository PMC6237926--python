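"""Equivalence-test scoring of recent relative yield growth.

A yield series *stagnates* over a test window if its annual relative
growth rates predominantly stay inside a stagnation interval
[L, U] = [0, 0.5%]/yr centred on a 0.25%/yr detection threshold.
Rather than a hard test, each window year receives a score in [0, 1]
from the position of the 90% confidence interval of the relative growth
rate relative to [L, U].  Each CI endpoint falls below L, within
[L, U], or above U; where the CI straddles a bound, the point
estimate's cell disambiguates — giving exactly ten reachable positions.
The overall score is the mean of the per-year scores; a series is
"likely stagnating" if the overall score is at least 0.5.  The onset
year is the first window year whose relative growth falls strictly
below U.

The default per-position scores are a monotone reconstruction expressing
confidence that true growth is below U; they are fully configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dlm import TrendFit
from .panel import YieldPanel

__all__ = [
    "StagnationConfig",
    "StagnationResult",
    "POSITION_LABELS",
    "DEFAULT_SCORE_TABLE",
    "classify_position",
    "stagnation_score",
    "onset_year",
    "area_share_stagnating",
    "compare_group_yields",
    "sensitivity_sweep",
]

#: The ten reachable CI positions, ordered from clear stagnation (P1,
#: CI wholly below the stagnation interval's upper bound region) to
#: clear growth (P10, CI wholly above).  Keys are the cells of
#: (low endpoint, high endpoint, point estimate) relative to [L, U]:
#: "b" below L, "i" inside [L, U], "a" above U.
POSITION_LABELS: dict[tuple[str, str, str], str] = {
    ("b", "b", "b"): "P1",
    ("b", "i", "b"): "P2",
    ("b", "i", "i"): "P3",
    ("i", "i", "i"): "P4",
    ("b", "a", "b"): "P5",
    ("b", "a", "i"): "P6",
    ("i", "a", "i"): "P7",
    ("b", "a", "a"): "P8",
    ("i", "a", "a"): "P9",
    ("a", "a", "a"): "P10",
}

#: Score = confidence that the true growth rate lies below U.
DEFAULT_SCORE_TABLE: dict[str, float] = {
    "P1": 1.0,
    "P2": 1.0,
    "P3": 1.0,
    "P4": 1.0,
    "P5": 0.75,
    "P6": 0.5,
    "P7": 0.5,
    "P8": 0.25,
    "P9": 0.25,
    "P10": 0.0,
}


@dataclass(frozen=True)
class StagnationConfig:
    """Interval, window and scoring parameters of the stagnation test."""

    interval: tuple[float, float] = (0.0, 0.005)  # [L, U], fraction/yr
    threshold: float = 0.0025  # centre of the interval, fraction/yr
    window: tuple[int, int] = (1997, 2016)  # inclusive test window
    likely_cutoff: float = 0.5
    score_table: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SCORE_TABLE)
    )

    def __post_init__(self) -> None:
        L, U = self.interval
        if not (L < self.threshold < U):
            raise ValueError("threshold must lie strictly inside the interval")
        if self.window[0] > self.window[1]:
            raise ValueError("empty test window")
        if any(not (0.0 <= s <= 1.0) for s in self.score_table.values()):
            raise ValueError("scores must lie in [0, 1]")


@dataclass
class StagnationResult:
    per_year: pd.DataFrame  # columns: year, position, score
    overall: float
    likely: bool
    onset_year: int | None
    n_years_scored: int


def _cell(x: float, L: float, U: float) -> str:
    if x < L:
        return "b"
    if x > U:
        return "a"
    return "i"


def classify_position(
    ci: tuple[float, float], point: float, interval: tuple[float, float]
) -> str:
    """Label the position of a growth-rate CI relative to [L, U].

    ``point`` must lie inside ``ci``; cells are strict below L and
    strict above U, inclusive inside.
    """
    low, high = ci
    if low > high:
        raise ValueError(f"invalid interval: low {low} > high {high}")
    if not (low <= point <= high):
        raise ValueError("point estimate must lie within its CI")
    L, U = interval
    key = (_cell(low, L, U), _cell(high, L, U), _cell(point, L, U))
    return POSITION_LABELS[key]


def stagnation_score(
    fit: TrendFit, cfg: StagnationConfig | None = None
) -> StagnationResult:
    """Score every window year of a fitted series and summarize.

    Years outside the fit's span are skipped; the overall score is the
    mean over scored years.  Raises ``ValueError`` if no window year has
    an estimate.
    """
    cfg = cfg or StagnationConfig()
    lo_y, hi_y = cfg.window
    mask = (fit.years >= lo_y) & (fit.years <= hi_y)
    if not mask.any():
        raise ValueError("trend fit covers no year of the test window")
    rows = []
    for i in np.flatnonzero(mask):
        if not np.isfinite(fit.g[i]):  # undefined rate that year
            continue
        pos = classify_position(
            (fit.g_lo[i], fit.g_hi[i]), fit.g[i], cfg.interval
        )
        rows.append((int(fit.years[i]), pos, float(cfg.score_table[pos])))
    if not rows:
        raise ValueError("no window year has a defined growth estimate")
    per_year = pd.DataFrame(rows, columns=["year", "position", "score"])
    overall = float(per_year["score"].mean())
    likely = overall >= cfg.likely_cutoff
    onset = onset_year(fit, cfg) if likely else None
    return StagnationResult(
        per_year=per_year, overall=overall, likely=likely,
        onset_year=onset, n_years_scored=len(per_year),
    )


def onset_year(fit: TrendFit, cfg: StagnationConfig | None = None) -> int | None:
    """First window year with relative growth strictly below U.

    Only meaningful for series classified as likely stagnating; returns
    None if no window year crosses below U.  Note the window start caps
    how early an onset can be detected.
    """
    cfg = cfg or StagnationConfig()
    U = cfg.interval[1]
    mask = (fit.years >= cfg.window[0]) & (fit.years <= cfg.window[1])
    for i in np.flatnonzero(mask):
        if fit.g[i] < U:
            return int(fit.years[i])
    return None


def area_share_stagnating(
    results: Mapping[str, StagnationResult],
    panel: YieldPanel,
    crop: str,
    season_type: str = "aggregate",
    window: tuple[int, int] = (1997, 2016),
) -> float:
    """Fraction of crop area (summed over departments) that stagnates.

    Each assessed department is weighted by its mean area over the
    window years with data; the share is the stagnating weight over the
    total assessed weight.
    """
    df = panel.df
    m = (
        (df["crop"] == crop)
        & (df["season_type"] == season_type)
        & df["year"].between(*window)
    )
    mean_area = df.loc[m].groupby("department_id")["area_ha"].mean()
    total = 0.0
    stagnating = 0.0
    for dept, res in results.items():
        w = float(mean_area.get(dept, np.nan))
        if np.isnan(w):
            continue
        total += w
        if res.likely:
            stagnating += w
    if total <= 0:
        raise ValueError("no area data for assessed departments")
    return stagnating / total


def compare_group_yields(
    stagnating: Sequence[float], non_stagnating: Sequence[float]
) -> dict:
    """Welch two-sample comparison of department mean yields.

    Returns group means, SDs, sizes, and the two-sided p-value of
    Welch's unequal-variance t-test.
    """
    a = np.asarray(stagnating, float)
    b = np.asarray(non_stagnating, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 departments")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    if np.isnan(p):  # both groups constant
        p = 1.0 if np.mean(a) == np.mean(b) else 0.0
    return {
        "mean_stagnating": float(np.mean(a)),
        "sd_stagnating": float(np.std(a, ddof=1)),
        "n_stagnating": len(a),
        "mean_non_stagnating": float(np.mean(b)),
        "sd_non_stagnating": float(np.std(b, ddof=1)),
        "n_non_stagnating": len(b),
        "t": float(t),
        "p": float(p),
    }


def sensitivity_sweep(
    fits: Mapping[str, TrendFit],
    panel: YieldPanel,
    crop: str,
    thresholds: Sequence[float],
    window_starts: Sequence[int],
    base_cfg: StagnationConfig | None = None,
    season_type: str = "aggregate",
) -> pd.DataFrame:
    """Recompute the stagnating area share over a grid of detection
    thresholds (interval centres; the interval is 0 to 2x the
    threshold) and window start years."""
    base_cfg = base_cfg or StagnationConfig()
    rows = []
    for thr in thresholds:
        for start in window_starts:
            cfg = replace(
                base_cfg,
                interval=(0.0, 2.0 * thr),
                threshold=thr,
                window=(start, base_cfg.window[1]),
            )
            results = {d: stagnation_score(f, cfg) for d, f in fits.items()}
            share = area_share_stagnating(
                results, panel, crop, season_type, window=cfg.window
            )
            rows.append((thr, start, share))
    return pd.DataFrame(rows, columns=["threshold", "window_start", "area_share"])
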