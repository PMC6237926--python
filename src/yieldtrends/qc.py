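"""Outlier screening for annual yield series.

Historical agricultural statistics contain occasional annotation errors
(slipped decimal points, transposed digits).  Three complementary rules
flag them:

``absolute``
    The yield exceeds an empirically chosen per-crop upper bound.
``mean_ratio``
    The yield is more than *k* times higher, or *k* times lower, than
    the long-term mean of its own (department, crop, season) series
    (k = 5 by default; maize 10; oats and soft wheat 6).
``jump``
    The yield is more than 20 times the value of the immediately
    preceding calendar year.

Flagged values are masked to missing rather than corrected, to avoid
introducing bias from any imputation scheme.  The screen is a single
pass: the long-term mean for ``mean_ratio`` includes the candidate
point, and flagging is never iterated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .panel import IntegrityError, YieldPanel

__all__ = ["OutlierRules", "QCReport", "flag_outliers", "apply_mask"]

#: Empirical per-crop upper yield bounds (t/ha; hl/ha for wine).
DEFAULT_ABSOLUTE_BOUNDS: dict[str, float] = {
    "soft_wheat": 10.0,
    "durum_wheat": 10.0,
    "barley": 10.0,
    "sugar_beet": 100.0,
    "maize": 15.0,
    "oats": 8.0,
    "potatoes": 60.0,
    "rapeseed": 5.0,
    "sunflower": 5.0,
    "wine": 200.0,
}

#: Ratio-vs-long-term-mean exceptions (default is 5).
DEFAULT_MEAN_RATIO_EXCEPTIONS: dict[str, float] = {
    "maize": 10.0,
    "oats": 6.0,
    "soft_wheat": 6.0,
}

REPORT_COLUMNS = (
    "department_id",
    "crop",
    "season_type",
    "year",
    "yield_t_ha",
    "rule",
)


@dataclass(frozen=True)
class OutlierRules:
    """Thresholds for the three outlier rules, keyed by crop."""

    absolute_bounds: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ABSOLUTE_BOUNDS)
    )
    mean_ratio_default: float = 5.0
    mean_ratio_exceptions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MEAN_RATIO_EXCEPTIONS)
    )
    jump_ratio: float = 20.0
    #: also flag >jump_ratio decreases; off by default (the screen
    #: targets implausible *increases*).
    jump_flags_decrease: bool = False

    def __post_init__(self) -> None:
        vals = list(self.absolute_bounds.values()) + [
            self.mean_ratio_default,
            self.jump_ratio,
            *self.mean_ratio_exceptions.values(),
        ]
        if any(v <= 0 for v in vals):
            raise ValueError("all outlier bounds and ratios must be positive")

    def mean_ratio(self, crop: str) -> float:
        return self.mean_ratio_exceptions.get(crop, self.mean_ratio_default)


@dataclass
class QCReport:
    """Flags produced by :func:`flag_outliers` plus summary fractions."""

    flags: pd.DataFrame  # columns REPORT_COLUMNS
    fraction_flagged: float
    fraction_by_crop: dict[str, float]

    def __len__(self) -> int:
        return len(self.flags)


def flag_outliers(
    panel: YieldPanel, rules: OutlierRules | None = None, strict: bool = True
) -> QCReport:
    """Scan every yield series and report rule violations.

    Each non-missing yield can be flagged by several rules; the report
    carries one row per (record, rule).  Flags are reported only — use
    :func:`apply_mask` to mask them.
    """
    rules = rules or OutlierRules()
    rows: list[tuple] = []
    n_values = 0
    n_values_by_crop: dict[str, int] = {}
    flagged_by_crop: dict[str, set] = {}

    for (dept, crop, season), g in panel.iter_series():
        if strict and crop not in rules.absolute_bounds:
            raise KeyError(f"no absolute yield bound configured for crop {crop!r}")
        bound = rules.absolute_bounds.get(crop, np.inf)
        k = rules.mean_ratio(crop)
        years = g["year"].to_numpy()
        y = g["yield_t_ha"].to_numpy()
        obs = ~np.isnan(y)
        n = int(obs.sum())
        n_values += n
        n_values_by_crop[crop] = n_values_by_crop.get(crop, 0) + n
        if n == 0:
            continue
        mean = float(np.nanmean(y))

        def _flag(i: int, rule: str) -> None:
            rows.append((dept, crop, season, int(years[i]), float(y[i]), rule))
            flagged_by_crop.setdefault(crop, set()).add((dept, season, int(years[i])))

        for i in np.flatnonzero(obs):
            v = y[i]
            if v > bound:
                _flag(i, "absolute")
            if mean > 0 and (v > k * mean or v < mean / k):
                _flag(i, "mean_ratio")
            # jump rule: compare with the immediately preceding calendar
            # year only; a gap disables the rule for this point.
            j = i - 1
            if j >= 0 and years[i] - years[j] == 1 and obs[j] and y[j] > 0:
                r = v / y[j]
                if r > rules.jump_ratio:
                    _flag(i, "jump")
                elif rules.jump_flags_decrease and r < 1.0 / rules.jump_ratio:
                    _flag(i, "jump")

    flags = pd.DataFrame(rows, columns=list(REPORT_COLUMNS))
    n_flagged_records = len(
        flags.drop_duplicates(subset=["department_id", "crop", "season_type", "year"])
    )
    frac = n_flagged_records / n_values if n_values else 0.0
    frac_by_crop = {
        crop: len(flagged_by_crop.get(crop, ())) / cnt if cnt else 0.0
        for crop, cnt in n_values_by_crop.items()
    }
    return QCReport(flags=flags, fraction_flagged=frac, fraction_by_crop=frac_by_crop)


def apply_mask(panel: YieldPanel, report: QCReport) -> YieldPanel:
    """Set every flagged yield to missing; area and production are kept.

    Idempotent: masking an already-masked panel changes nothing.
    """
    if report.flags.empty:
        return panel.copy()
    df = panel.df.copy()
    keys = df.set_index(["department_id", "crop", "season_type", "year"]).index
    flag_keys = pd.MultiIndex.from_frame(
        report.flags[["department_id", "crop", "season_type", "year"]]
    )
    unknown = flag_keys.difference(keys)
    if len(unknown):
        raise IntegrityError(
            f"QC report references {len(unknown)} keys absent from panel, "
            f"e.g. {unknown[0]}"
        )
    df.loc[keys.isin(flag_keys), "yield_t_ha"] = np.nan
    return YieldPanel(df, panel.units, panel.provenance, panel.year_range)
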