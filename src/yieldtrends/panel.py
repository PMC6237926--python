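"""Data model and I/O for long-format annual crop-yield panels.

A *yield panel* is a long table of annual records keyed by
``(department_id, crop, season_type, year)`` carrying harvested area
(hectares), production (tonnes; hectolitres for wine) and yield
(tonnes per hectare; hectolitres per hectare for wine).  Yields are
always derivable as ``production / area``; printed yields in historical
statistics are unreliable, so :func:`derive_yields` recomputes them.

Department boundaries changed during the 20th century.
:class:`DepartmentMap` expresses the two harmonization idioms needed for
a long panel: *splits* (one historical unit succeeded by several modern
ones; pre-split yields are copied to each successor) and *merges*
(several historical units treated as one counterfactual unit up to an
end year, with pooled area and production).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CROPS",
    "SEASON_TYPES",
    "PANEL_COLUMNS",
    "KEY_COLUMNS",
    "YieldPanel",
    "SplitRule",
    "MergeRule",
    "DepartmentMap",
    "PanelError",
    "SchemaError",
    "IntegrityError",
    "MappingError",
    "read_panel",
    "derive_yields",
    "harmonize_departments",
    "write_results",
]

logger = logging.getLogger(__name__)

#: Crops covered by the analysis.  Wine is measured in hl (production)
#: and hl/ha (yield); everything else in tonnes and t/ha.
CROPS = (
    "barley",
    "soft_wheat",
    "durum_wheat",
    "maize",
    "oats",
    "potatoes",
    "rapeseed",
    "sugar_beet",
    "sunflower",
    "wine",
)

SEASON_TYPES = ("spring", "winter", "aggregate")

PANEL_COLUMNS = (
    "department_id",
    "crop",
    "season_type",
    "year",
    "area_ha",
    "production_t",
    "yield_t_ha",
)
KEY_COLUMNS = ("department_id", "crop", "season_type", "year")

DEFAULT_YEAR_RANGE = (1900, 2016)


class PanelError(ValueError):
    """Base class for panel validation failures."""


class SchemaError(PanelError):
    """A required column is missing or unparseable."""


class IntegrityError(PanelError):
    """Duplicate keys or cross-field inconsistencies."""


class MappingError(PanelError):
    """A department-harmonization rule references an unknown unit."""


@dataclass
class YieldPanel:
    """Long-format panel of annual (department, crop) yield records.

    Wraps a :class:`pandas.DataFrame` with columns :data:`PANEL_COLUMNS`
    and enforces key uniqueness and basic record invariants on
    construction.  Missing values are NaN; zeros are legal areas and are
    never used to encode missingness.
    """

    df: pd.DataFrame
    units: Mapping[str, str] = field(default_factory=dict)
    provenance: str = ""
    year_range: tuple[int, int] = DEFAULT_YEAR_RANGE

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in PANEL_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"panel is missing columns: {missing}")
        df = df.loc[:, list(PANEL_COLUMNS)].copy()
        df["year"] = df["year"].astype(int)
        for col in ("area_ha", "production_t", "yield_t_ha"):
            df[col] = pd.to_numeric(df[col], errors="raise").astype(float)
        dup = df.duplicated(subset=list(KEY_COLUMNS))
        if dup.any():
            bad = df.loc[dup, list(KEY_COLUMNS)].iloc[0].tolist()
            raise IntegrityError(f"duplicate panel key: {tuple(bad)}")
        lo, hi = self.year_range
        out = ~df["year"].between(lo, hi)
        if out.any():
            raise IntegrityError(
                f"{int(out.sum())} records outside year range {lo}-{hi}"
            )
        for col in ("area_ha", "production_t", "yield_t_ha"):
            if (df[col].dropna() < 0).any():
                raise IntegrityError(f"negative values in {col}")
        df = df.sort_values(list(KEY_COLUMNS), kind="mergesort").reset_index(drop=True)
        object.__setattr__(self, "df", df)

    def __len__(self) -> int:
        return len(self.df)

    def copy(self) -> "YieldPanel":
        return YieldPanel(
            self.df.copy(), dict(self.units), self.provenance, self.year_range
        )

    def series(
        self, department_id: str, crop: str, season_type: str
    ) -> pd.DataFrame:
        """Return the annual records of one (department, crop, season)."""
        m = (
            (self.df["department_id"] == department_id)
            & (self.df["crop"] == crop)
            & (self.df["season_type"] == season_type)
        )
        return self.df.loc[m].sort_values("year")

    def iter_series(self) -> Iterable[tuple[tuple[str, str, str], pd.DataFrame]]:
        for key, g in self.df.groupby(
            ["department_id", "crop", "season_type"], sort=True
        ):
            yield key, g.sort_values("year")

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False, float_format="%.10g")


@dataclass(frozen=True)
class SplitRule:
    """One historical department succeeded by several modern ones.

    Pre-split yields are copied to every successor; areas and
    productions are divided among successors according to
    ``area_policy`` ("equal" shares by default, or "copy").
    """

    parent: str
    successors: tuple[str, ...]
    split_year: int  # first year in which the successors report themselves
    area_policy: str = "equal"


@dataclass(frozen=True)
class MergeRule:
    """Several historical departments pooled into one counterfactual unit
    up to and including ``end_year`` (area and production summed, yield
    recomputed)."""

    members: tuple[str, ...]
    unit: str
    end_year: int


@dataclass(frozen=True)
class DepartmentMap:
    splits: tuple[SplitRule, ...] = ()
    merges: tuple[MergeRule, ...] = ()

    def __post_init__(self) -> None:
        split_depts = {r.parent for r in self.splits}
        merge_depts = {m for r in self.merges for m in r.members}
        for d in split_depts & merge_depts:
            for s in self.splits:
                if s.parent != d:
                    continue
                for m in self.merges:
                    if d in m.members and m.end_year >= s.split_year:
                        raise MappingError(
                            f"department {d} in overlapping split and merge rules"
                        )


def read_panel(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    units: Mapping[str, str] | None = None,
    year_range: tuple[int, int] = DEFAULT_YEAR_RANGE,
) -> YieldPanel:
    """Read a long-format CSV into a :class:`YieldPanel`.

    Parameters
    ----------
    path
        CSV file with a header; missing values are empty fields.
    schema
        Optional mapping from panel column names to the file's column
        names, e.g. ``{"area_ha": "surface"}``.  Identity by default.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, dtype={0: str})
    colmap = {c: c for c in PANEL_COLUMNS}
    if schema:
        colmap.update(schema)
    missing = [src for src in colmap.values() if src not in raw.columns]
    if missing:
        raise SchemaError(f"input file lacks required columns: {missing}")
    df = pd.DataFrame({dst: raw[src] for dst, src in colmap.items()})
    df["department_id"] = df["department_id"].astype(str)
    n_bad = 0
    for col in ("area_ha", "production_t", "yield_t_ha"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        n_bad += int((coerced.isna() & df[col].notna()).sum())
        df[col] = coerced
    if n_bad:
        logger.warning("read_panel: %d unparseable numeric cells set missing", n_bad)
    return YieldPanel(df, units=dict(units or {}), provenance=str(path),
                      year_range=year_range)


def derive_yields(panel: YieldPanel) -> YieldPanel:
    """Recompute yield = production / area for every record.

    Pre-existing yield values are overwritten: printed yields in old
    statistics are frequently wrong, while production and area are more
    reliable.  The yield is missing wherever area is zero or either
    input is missing.
    """
    df = panel.df.copy()
    area = df["area_ha"].to_numpy()
    prod = df["production_t"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        y = prod / area
    y[~np.isfinite(y)] = np.nan
    y[np.isnan(area) | np.isnan(prod) | (area == 0)] = np.nan
    df["yield_t_ha"] = y
    return YieldPanel(df, panel.units, panel.provenance, panel.year_range)


def _apply_split(df: pd.DataFrame, rule: SplitRule) -> pd.DataFrame:
    pre = df[(df["department_id"] == rule.parent) & (df["year"] < rule.split_year)]
    rest = df[~((df["department_id"] == rule.parent) & (df["year"] < rule.split_year))]
    if pre.empty:
        return df
    share = 1.0 / len(rule.successors) if rule.area_policy == "equal" else 1.0
    pieces = []
    for succ in rule.successors:
        p = pre.copy()
        p["department_id"] = succ
        p["area_ha"] = p["area_ha"] * share
        p["production_t"] = p["production_t"] * share
        # yields are copied verbatim to each successor
        pieces.append(p)
    return pd.concat([rest] + pieces, ignore_index=True)


def _apply_merge(df: pd.DataFrame, rule: MergeRule) -> pd.DataFrame:
    m = df["department_id"].isin(rule.members) & (df["year"] <= rule.end_year)
    pre, rest = df[m], df[~m]
    if pre.empty:
        return df
    g = pre.groupby(["crop", "season_type", "year"], as_index=False).agg(
        area_ha=("area_ha", lambda s: s.sum(min_count=1)),
        production_t=("production_t", lambda s: s.sum(min_count=1)),
    )
    g["department_id"] = rule.unit
    with np.errstate(divide="ignore", invalid="ignore"):
        y = g["production_t"] / g["area_ha"]
    g["yield_t_ha"] = y.where(np.isfinite(y) & (g["area_ha"] > 0))
    return pd.concat([rest, g[list(PANEL_COLUMNS)]], ignore_index=True)


def harmonize_departments(
    panel: YieldPanel, dep_map: DepartmentMap, strict: bool = False
) -> YieldPanel:
    """Apply split and merge rules so that the panel uses one consistent
    set of spatial units across the whole record."""
    df = panel.df
    known = set(df["department_id"].unique())
    for rule in dep_map.splits:
        if rule.parent not in known:
            if strict:
                raise MappingError(f"split rule references unknown unit {rule.parent}")
            continue
        df = _apply_split(df, rule)
    known = set(df["department_id"].unique())
    for rule in dep_map.merges:
        absent = [m for m in rule.members if m not in known]
        if absent:
            if strict:
                raise MappingError(f"merge rule references unknown units {absent}")
            if len(absent) == len(rule.members):
                continue
        df = _apply_merge(df, rule)
    return YieldPanel(df, panel.units, panel.provenance, panel.year_range)


def write_results(
    tables: Mapping[str, pd.DataFrame],
    directory: str | Path,
    config: Mapping | None = None,
    seed: int | None = None,
) -> dict:
    """Write one CSV per table plus a JSON run manifest.

    The manifest records a hash of the configuration, the seed and the
    package version; rerunning with identical inputs produces
    byte-identical files (rows are written as given, floats with
    ``%.10g``, no timestamps).
    """
    from . import __version__

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": hashlib.sha256(
            json.dumps(config or {}, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seed": seed,
        "version": __version__,
        "tables": {},
    }
    for name in sorted(tables):
        out = directory / f"{name}.csv"
        tables[name].to_csv(out, index=False, float_format="%.10g")
        manifest["tables"][name] = {
            "rows": int(len(tables[name])),
            "sha256": hashlib.sha256(out.read_bytes()).hexdigest(),
        }
    (directory / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
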