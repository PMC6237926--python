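"""National aggregation, decadal growth categorization and the
small-area sensitivity filter.

National yield series are area-weighted means across departments; a
department contributes in a year only if it reports both yield and
area.  Decadal growth-rate categories summarize the distribution of
relative growth over time across all crop-department series; per-decade
counts are normalized so that the categories of each decade sum to one.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dlm import TrendFit
from .panel import YieldPanel

__all__ = [
    "DEFAULT_GROWTH_EDGES",
    "national_aggregate",
    "decadal_growth_categories",
    "filter_small_area",
]

logger = logging.getLogger(__name__)

#: Relative-growth category edges (fraction/yr): category 1 is
#: non-positive growth, the 0.25%/yr stagnation detection threshold is
#: a bin edge, category 5 is growth above 3%/yr.
DEFAULT_GROWTH_EDGES = (0.0, 0.0025, 0.01, 0.03)


def national_aggregate(
    panel: YieldPanel, crop: str, season_type: str = "aggregate"
) -> pd.DataFrame:
    """Area-weighted national mean yield per year for one crop.

    Columns: year, mean_yield, n_depts, total_area.  Years without any
    contributing department are absent from the output.
    """
    df = panel.df
    m = (
        (df["crop"] == crop)
        & (df["season_type"] == season_type)
        & df["yield_t_ha"].notna()
        & df["area_ha"].notna()
        & (df["area_ha"] > 0)
    )
    sub = df.loc[m]
    rows = []
    for year, g in sub.groupby("year"):
        w = g["area_ha"].to_numpy()
        v = g["yield_t_ha"].to_numpy()
        rows.append(
            (int(year), float(np.average(v, weights=w)), len(v), float(w.sum()))
        )
    return pd.DataFrame(
        rows, columns=["year", "mean_yield", "n_depts", "total_area"]
    ).sort_values("year").reset_index(drop=True)


def decadal_growth_categories(
    fits: Mapping[tuple[str, str], TrendFit],
    edges: Sequence[float] = DEFAULT_GROWTH_EDGES,
    exclude_crops: Sequence[str] = ("wine",),
    year_range: tuple[int, int] = (1900, 2016),
) -> pd.DataFrame:
    """Bin decade-mean relative growth rates of all series into 5
    categories and normalize counts per decade.

    ``fits`` maps (crop, department) to a trend fit.  Wine is excluded
    by default: its growth is administratively capped and would blur
    the agronomic picture.  Columns: decade, category, count,
    normalized_area (count over the decade total, summing to 1).
    """
    edges = tuple(edges)
    if list(edges) != sorted(edges) or len(edges) != 4:
        raise ValueError("need 4 strictly increasing category edges")
    rows = []
    for (crop, dept), fit in fits.items():
        if crop in exclude_crops:
            continue
        start = (year_range[0] // 10) * 10
        while start <= year_range[1]:
            sel = (fit.years >= start) & (fit.years <= min(start + 9, year_range[1]))
            if sel.any():
                gbar = float(np.mean(fit.g[sel]))
                cat = int(np.searchsorted(edges, gbar, side="left")) + 1
                rows.append((start, cat))
            start += 10
    df = pd.DataFrame(rows, columns=["decade", "category"])
    out = []
    for decade, g in df.groupby("decade"):
        counts = g["category"].value_counts()
        total = int(counts.sum())
        for cat in range(1, 6):
            c = int(counts.get(cat, 0))
            out.append((int(decade), cat, c, c / total))
    return pd.DataFrame(
        out, columns=["decade", "category", "count", "normalized_area"]
    )


def filter_small_area(
    panel: YieldPanel, crop: str, q: float = 0.10, min_departments: int = 10
) -> YieldPanel:
    """Drop departments whose long-term mean area for ``crop`` falls
    below the q-quantile of mean areas across departments.

    Used as a sensitivity check: conclusions should not hinge on
    departments that barely grow the crop.  Other crops' records are
    untouched.  With fewer than ``min_departments`` reporting
    departments the filter is skipped with a warning.
    """
    df = panel.df
    m = (df["crop"] == crop) & df["area_ha"].notna()
    mean_area = df.loc[m].groupby("department_id")["area_ha"].mean()
    if len(mean_area) < min_departments:
        logger.warning(
            "filter_small_area: only %d departments for %s; filter skipped",
            len(mean_area), crop,
        )
        return panel.copy()
    if q <= 0:
        return panel.copy()
    cutoff = float(np.quantile(mean_area.to_numpy(), q, method="linear"))
    drop = set(mean_area.index[mean_area < cutoff])
    keep = ~((df["crop"] == crop) & df["department_id"].isin(drop))
    out = df.loc[keep].reset_index(drop=True)
    return YieldPanel(out, panel.units, panel.provenance, panel.year_range)
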