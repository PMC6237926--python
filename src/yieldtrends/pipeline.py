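"""End-to-end orchestration: QC -> trend fits -> stagnation,
variability, clustering, drivers -> national aggregation -> sensitivity.

Every stage writes one or more CSV tables plus a manifest recording the
configuration hash, the seed and per-stage counts.  Per-series failures
(too few observations, degenerate series) are logged and skipped; they
never corrupt other series' outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
import numpy as np
import pandas as pd

from . import aggregation, clustering, qc, stagnation, variability
from .dlm import InsufficientData, TrendFit, fit_dlm
from .drivers import DriverSeries, driver_correlation, summarize_driver_correlations
from .panel import YieldPanel, write_results
from .synthetic import Scenario, generate_drivers, generate_panel

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "combine_season_types"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Stage toggles and parameters for a full pipeline run."""

    scenario: Scenario | None = None  # synthetic input; else provide a panel
    seed: int = 0
    out_dir: str | None = None
    min_obs: int = 30
    qc_rules: qc.OutlierRules = field(default_factory=qc.OutlierRules)
    stagnation_cfg: stagnation.StagnationConfig = field(
        default_factory=stagnation.StagnationConfig
    )
    eras: tuple = clustering.DEFAULT_ERAS
    small_area_q: float = 0.10
    run_qc: bool = True
    run_stagnation: bool = True
    run_variability: bool = True
    run_clustering: bool = True
    run_drivers: bool = True
    run_aggregation: bool = True
    run_sensitivity: bool = False


@dataclass
class PipelineResult:
    panel: YieldPanel
    fits: dict[tuple[str, str, str], TrendFit]  # (crop, season, dept)
    tables: dict[str, pd.DataFrame]
    counts: dict[str, int]
    stagnation_results: dict[tuple[str, str, str], stagnation.StagnationResult]
    manifest: dict | None = None


def combine_season_types(panel: YieldPanel) -> YieldPanel:
    """Add area-weighted 'aggregate' records where a (department, crop,
    year) has both a spring and a winter record but no aggregate one.

    The combined yield keeps rising when a lower-yielding spring
    cultivar is replaced in area by a higher-yielding winter one, even
    if neither cultivar improves — which is why season types are both
    analyzed separately and combined.
    """
    df = panel.df
    seasonal = df[df["season_type"].isin(["spring", "winter"])]
    if seasonal.empty:
        return panel.copy()
    have_agg = set(
        map(tuple, df.loc[df["season_type"] == "aggregate",
                          ["department_id", "crop", "year"]].itertuples(index=False))
    )
    g = seasonal.groupby(["department_id", "crop", "year"], as_index=False).agg(
        area_ha=("area_ha", lambda s: s.sum(min_count=1)),
        production_t=("production_t", lambda s: s.sum(min_count=1)),
        n=("season_type", "count"),
    )
    g = g[g["n"] >= 2]
    g = g[~g.apply(lambda r: (r["department_id"], r["crop"], r["year"]) in have_agg,
                   axis=1)] if have_agg else g
    if g.empty:
        return panel.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        y = g["production_t"] / g["area_ha"]
    g["yield_t_ha"] = y.where(np.isfinite(y) & (g["area_ha"] > 0))
    g["season_type"] = "aggregate"
    out = pd.concat([df, g.drop(columns="n")], ignore_index=True)
    return YieldPanel(out, panel.units, panel.provenance, panel.year_range)


def _fit_all(
    panel: YieldPanel, min_obs: int
) -> tuple[dict[tuple[str, str, str], TrendFit], int]:
    fits: dict[tuple[str, str, str], TrendFit] = {}
    skipped = 0
    for (dept, crop, season), g in panel.iter_series():
        y = g["yield_t_ha"].to_numpy()
        years = g["year"].to_numpy()
        try:
            _, fit = fit_dlm(y, years=years, min_obs=min_obs)
        except InsufficientData:
            skipped += 1
            logger.info("skipping %s/%s/%s: < %d observations",
                        dept, crop, season, min_obs)
            continue
        except Exception as exc:  # keep other series alive
            skipped += 1
            logger.warning("fit failed for %s/%s/%s: %s", dept, crop, season, exc)
            continue
        fits[(crop, season, dept)] = fit
    return fits, skipped


def run_pipeline(cfg: RunConfig, panel: YieldPanel | None = None,
                 drivers: list[DriverSeries] | None = None) -> PipelineResult:
    """Execute the configured stages and return all result tables."""
    truth = None
    if panel is None:
        if cfg.scenario is None:
            raise ValueError("provide either a panel or a scenario")
        panel, truth = generate_panel(cfg.scenario)
        if drivers is None and cfg.run_drivers:
            drivers = generate_drivers(cfg.scenario, truth)
    panel = combine_season_types(panel)
    tables: dict[str, pd.DataFrame] = {}
    counts: dict[str, int] = {}

    if cfg.run_qc:
        report = qc.flag_outliers(panel, cfg.qc_rules)
        panel = qc.apply_mask(panel, report)
        tables["qc_flags"] = report.flags
        counts["outliers_masked"] = len(report.flags)

    fits, skipped = _fit_all(panel, cfg.min_obs)
    counts["series_fitted"] = len(fits)
    counts["series_skipped"] = skipped
    trend_rows = []
    for (crop, season, dept), f in fits.items():
        trend_rows.append(pd.DataFrame({
            "crop": crop, "season_type": season, "department_id": dept,
            "year": f.years, "a": f.a, "var_a": f.var_a, "b": f.b,
            "var_b": f.var_b, "g": f.g, "g_lo": f.g_lo, "g_hi": f.g_hi,
        }))
    if trend_rows:
        tables["trends"] = pd.concat(trend_rows, ignore_index=True)

    stag_results: dict[tuple[str, str, str], stagnation.StagnationResult] = {}
    if cfg.run_stagnation:
        rows = []
        for key, f in fits.items():
            try:
                res = stagnation.stagnation_score(f, cfg.stagnation_cfg)
            except ValueError:
                continue
            stag_results[key] = res
            rows.append((*key, res.overall, res.likely, res.onset_year,
                         res.n_years_scored))
        tables["stagnation"] = pd.DataFrame(
            rows, columns=["crop", "season_type", "department_id",
                           "overall_score", "likely", "onset_year", "n_years"]
        )
        share_rows = []
        for (crop, season) in sorted({(c, s) for (c, s, _) in stag_results}):
            per_dept = {d: r for (c, s, d), r in stag_results.items()
                        if c == crop and s == season}
            try:
                share = stagnation.area_share_stagnating(
                    per_dept, panel, crop, season,
                    window=cfg.stagnation_cfg.window,
                )
            except ValueError:
                continue
            share_rows.append((crop, season, share, len(per_dept)))
        tables["stagnating_area_share"] = pd.DataFrame(
            share_rows, columns=["crop", "season_type", "area_share", "n_depts"]
        )

    if cfg.run_variability:
        all_stats: list[variability.DecadeStat] = []
        resid_rows = []
        for (crop, season, dept), f in fits.items():
            g = panel.series(dept, crop, season)
            y = g["yield_t_ha"].to_numpy()
            years = g["year"].to_numpy()
            res = variability.residuals(years, y, f)
            stats_ = variability.decadal_cv(
                crop, dept, res, years, y, year_range=panel.year_range
            )
            all_stats.extend(stats_)
            for yr, rv in zip(res.years, res.values):
                resid_rows.append((crop, season, dept, int(yr), float(rv)))
        tables["decadal_cv"] = pd.DataFrame(
            [(s.crop, s.department_id, s.decade, s.mean_yield, s.sd_resid,
              s.cv, s.cv_category, s.n) for s in all_stats],
            columns=["crop", "department_id", "decade", "mean_yield",
                     "sd_resid", "cv", "category", "n"],
        )
        tables["residuals"] = pd.DataFrame(
            resid_rows,
            columns=["crop", "season_type", "department_id", "year", "residual"],
        )

    if cfg.run_clustering:
        rows = []
        for crop in sorted({c for (c, _, _) in fits}):
            for era in cfg.eras:
                means = clustering.era_mean_yields(panel, crop, era)
                if len(means) < 4:
                    continue
                try:
                    kept = clustering.trim_extremes(means, 0.01)
                    dropped = tuple(sorted(set(means.index) - set(kept.index)))
                    result = clustering.upgma_cluster(
                        kept, crop=crop, era=era, unclustered=dropped
                    )
                except ValueError:
                    continue
                for dept, lab in result.assignment.items():
                    rows.append((crop, era[0], era[1], dept, lab,
                                 result.cluster_means[lab], result.k,
                                 result.ch_curve.get(result.k, np.nan)))
        tables["clusters"] = pd.DataFrame(
            rows, columns=["crop", "era_start", "era_end", "department_id",
                           "cluster", "cluster_mean_yield", "k", "ch_at_k"]
        )

    if cfg.run_drivers and drivers:
        rows = []
        by_dept: dict[str, list[DriverSeries]] = {}
        for ds in drivers:
            by_dept.setdefault(ds.department_id, []).append(ds)
        for (crop, season, dept), f in fits.items():
            g = panel.series(dept, crop, season)
            for ds in by_dept.get(dept, []):
                for mode in ("raw", "detrended"):
                    try:
                        res = driver_correlation(
                            g["year"].to_numpy(), g["yield_t_ha"].to_numpy(),
                            ds, mode=mode,
                        )
                    except ValueError:
                        continue
                    rows.append((crop, ds.driver, dept, mode, res["r"],
                                 res["p"], res["n_years"]))
        tables["driver_correlations"] = pd.DataFrame(
            rows, columns=["crop", "driver", "department_id", "mode",
                           "r", "p", "n_years"]
        )
        summ = []
        dc = tables["driver_correlations"]
        for (crop, driver, mode), g in dc.groupby(["crop", "driver", "mode"]):
            per = {row.department_id: {"r": row.r, "p": row.p}
                   for row in g.itertuples()}
            s = summarize_driver_correlations(per, crop, driver)
            summ.append((crop, driver, mode, s["mean_r"],
                         s["share_significant"], s["n_departments"]))
        tables["driver_summary"] = pd.DataFrame(
            summ, columns=["crop", "driver", "mode", "mean_r",
                           "share_significant", "n_departments"]
        )

    if cfg.run_aggregation:
        nat_rows = []
        for crop in sorted({c for (c, _, _) in fits}):
            for season in sorted({s for (c, s, _) in fits if c == crop}):
                nat = aggregation.national_aggregate(panel, crop, season)
                nat.insert(0, "season_type", season)
                nat.insert(0, "crop", crop)
                nat_rows.append(nat)
        if nat_rows:
            tables["national_series"] = pd.concat(nat_rows, ignore_index=True)
        cd_fits = {(c, d): f for (c, s, d), f in fits.items()}
        if cd_fits:
            tables["growth_categories"] = aggregation.decadal_growth_categories(
                cd_fits, year_range=panel.year_range
            )

    manifest = None
    if cfg.out_dir is not None:
        cfg_dict = {k: str(v) for k, v in asdict(cfg).items()}
        manifest = write_results(tables, Path(cfg.out_dir), config=cfg_dict,
                                 seed=cfg.seed)
        manifest["counts"] = counts

    return PipelineResult(panel=panel, fits=fits, tables=tables, counts=counts,
                          stagnation_results=stag_results, manifest=manifest)
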