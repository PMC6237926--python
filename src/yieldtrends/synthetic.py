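"""Synthetic yield panels with the statistical structure of a
century-long subnational crop panel.

The generator emulates the features the analysis pipeline assumes,
with ground truth for every one of them:

* sigmoid mean-yield growth per crop and department (roughly four-fold
  over the century), with per-department level factors;
* *stagnating* series whose trend is frozen at its value in an onset
  year (default 1997), versus *growing* series whose logistic midpoint
  is late enough that relative growth stays above 1%/yr through the
  end of the record;
* heteroscedastic, left-skewed noise: skew-normal with mean zero,
  standard deviation following a Taylor power law
  ``sd = alpha * level**beta`` and a target skewness (default -0.2);
* multiplicative war-period dips (floor 0.7 over 1914-18 and 1939-45,
  with a half-depth first year and a three-year linear recovery, since
  wartime collapse and recovery of production were gradual);
* elevated wartime missingness (many departments stopped reporting
  during occupations) on top of a baseline missing rate;
* missing values and ~2% injected outliers that violate the three
  quality-screen rules by construction;
* per-department crop areas and department-level fertilizer series
  built as scaled trend plus noise calibrated to a target Pearson
  correlation.

All randomness derives from the single ``Scenario.seed``; identical
scenarios produce bit-identical panels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .drivers import DriverSeries
from .panel import PANEL_COLUMNS, YieldPanel
from .qc import DEFAULT_ABSOLUTE_BOUNDS, OutlierRules

__all__ = [
    "CropScenario",
    "Scenario",
    "GroundTruth",
    "generate_panel",
    "generate_drivers",
    "reference_fixture",
    "skewnorm_shape",
]

WAR_PERIODS_DEFAULT = ((1914, 1918, 0.7), (1939, 1945, 0.7))


@dataclass(frozen=True)
class CropScenario:
    """Trend family for one crop.

    Stagnating departments follow a mid-century logistic
    (midpoint ``t0_stag``, rate ``k_stag``) frozen at its
    ``stagnation_onset`` value; growing departments follow a
    late-midpoint logistic (``t0_grow``, ``k_grow``) whose relative
    growth stays above ~1%/yr to the end of the record.
    ``stagnating_area_share`` is the target fraction of the crop's
    total area assigned to stagnating departments.
    """

    crop: str
    y0: float
    ymax: float
    season_type: str = "aggregate"
    t0_stag: float = 1958.0
    k_stag: float = 0.09
    t0_grow: float = 2000.0
    k_grow: float = 0.06
    stagnating_area_share: float = 0.0
    stagnation_onset: int = 1997

    def __post_init__(self) -> None:
        if not (self.ymax > self.y0 > 0):
            raise ValueError(f"{self.crop}: need ymax > y0 > 0")
        if not (0.0 <= self.stagnating_area_share <= 1.0):
            raise ValueError(f"{self.crop}: invalid stagnating_area_share")


DEFAULT_CROPS = (
    CropScenario("soft_wheat", y0=1.8, ymax=7.2, stagnating_area_share=0.6),
    CropScenario("barley", y0=1.7, ymax=6.8, stagnating_area_share=0.4),
    CropScenario("maize", y0=2.2, ymax=8.8, stagnating_area_share=0.0),
)

#: Plateau of the growing (late-midpoint) profile, relative to y0.
GROW_YMAX_FACTOR = {"soft_wheat": 10.0 / 1.8, "barley": 9.5 / 1.7,
                    "maize": 11.0 / 2.2}


@dataclass(frozen=True)
class Scenario:
    """Full specification of a synthetic panel."""

    n_departments: int = 20
    crops: tuple[CropScenario, ...] = DEFAULT_CROPS
    years: tuple[int, int] = (1900, 2016)
    noise_alpha: float = 0.08
    noise_beta: float = 0.7
    skewness: float = -0.2
    war_periods: tuple[tuple[int, int, float], ...] = WAR_PERIODS_DEFAULT
    missing_rate: float = 0.05
    #: probability that a war-period value is missing (occupied or
    #: disrupted departments did not report)
    war_missing_rate: float = 0.7
    outlier_rate: float = 0.02
    #: per-department multiplicative level factor exp(U(-s, s))
    dept_spread: float = 0.14
    #: lognormal area model: exp(N(mu, sd)) hectares
    area_log_mean: float = 9.5
    area_log_sd: float = 0.5
    driver_targets: Mapping[str, float] = field(
        default_factory=lambda: {"N": 0.72, "K2O": 0.34, "P2O5": 0.0}
    )
    driver_span: tuple[int, int] = (1946, 2013)
    seed: int = 0

    def __post_init__(self) -> None:
        errors = []
        if self.n_departments < 1:
            errors.append("n_departments must be >= 1")
        if not (0.0 < self.noise_beta <= 1.0):
            errors.append("noise_beta must lie in (0, 1]")
        for name in ("missing_rate", "outlier_rate", "war_missing_rate"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                errors.append(f"{name} must lie in [0, 1]")
        if self.noise_alpha < 0:
            errors.append("noise_alpha must be >= 0")
        if abs(self.skewness) > 0.95:
            errors.append("skewness target outside skew-normal range")
        for d, r in self.driver_targets.items():
            if not (0.0 <= r < 1.0):
                errors.append(f"driver target r for {d} must lie in [0, 1)")
        if errors:
            raise ValueError("invalid scenario: " + "; ".join(errors))


@dataclass
class GroundTruth:
    """What the generator actually built, keyed by (crop, department)."""

    years: np.ndarray
    trend: dict[tuple[str, str], np.ndarray]  # war-free trend level
    growth: dict[tuple[str, str], np.ndarray]  # true relative growth
    stagnating: dict[tuple[str, str], bool]
    onset: dict[tuple[str, str], int | None]
    outliers: pd.DataFrame  # department_id, crop, season_type, year, rule
    stagnating_area_share: dict[str, float]  # achieved, by construction
    taylor_alpha: float
    taylor_beta: float
    skewness_target: float
    driver_targets: dict[str, float]


def skewnorm_shape(target_skewness: float) -> tuple[float, float, float]:
    """Skew-normal shape for a target skewness, via the moment formula.

    Returns (shape a, mean m, sd s) of the unit-scale skew-normal so
    that ``(X - m) / s`` has mean 0, variance 1 and the target
    skewness.
    """
    g = float(target_skewness)
    if g == 0.0:
        return 0.0, 0.0, 1.0
    u = np.cbrt(2.0 * g / (4.0 - np.pi))
    m_del = u / np.sqrt(1.0 + u * u)  # delta * sqrt(2/pi)
    delta = m_del * np.sqrt(np.pi / 2.0)
    if abs(delta) >= 1.0:
        raise ValueError("skewness outside the skew-normal range")
    a = delta / np.sqrt(1.0 - delta * delta)
    m = m_del
    s = np.sqrt(1.0 - m_del * m_del)
    return float(a), float(m), float(s)


def _logistic(years: np.ndarray, y0: float, ymax: float, t0: float,
              k: float) -> np.ndarray:
    return y0 + (ymax - y0) / (1.0 + np.exp(-k * (years - t0)))


def _war_profile(
    years: np.ndarray, periods: tuple[tuple[int, int, float], ...]
) -> tuple[np.ndarray, np.ndarray]:
    """Multiplicative war factor per year and a war-period mask.

    The first war year carries half the dip (harvests were partly in
    before mobilization), the remaining war years the full factor, and
    the three post-war years a linear recovery back to 1.
    """
    war = np.ones(len(years))
    inwar = np.zeros(len(years), dtype=bool)
    for w0, w1, f in periods:
        m = (years >= w0) & (years <= w1)
        war[m] = f
        war[years == w0] = (1.0 + f) / 2.0
        inwar |= m
        for dy in (1, 2, 3):
            m2 = years == w1 + dy
            war[m2] = np.minimum(war[m2], f + (1.0 - f) * dy / 4.0)
    return war, inwar


def _trend_for(cs: CropScenario, years: np.ndarray, stagnating: bool) -> np.ndarray:
    if stagnating:
        tr = _logistic(years, cs.y0, cs.ymax, cs.t0_stag, cs.k_stag)
        onset_val = _logistic(
            np.array([cs.stagnation_onset]), cs.y0, cs.ymax, cs.t0_stag, cs.k_stag
        )[0]
        tr = np.where(years >= cs.stagnation_onset, onset_val, tr)
    else:
        ymax = cs.y0 * GROW_YMAX_FACTOR.get(cs.crop, 4.5)
        tr = _logistic(years, cs.y0, ymax, cs.t0_grow, cs.k_grow)
    return tr


def _relative_growth(trend: np.ndarray) -> np.ndarray:
    g = np.empty_like(trend)
    g[:-1] = np.diff(trend) / trend[:-1]
    g[-1] = g[-2]
    return g


def _assign_stagnating(
    rng: np.random.Generator, depts: list[str], areas: np.ndarray, target: float
) -> tuple[set[str], float]:
    """Pick departments (in random order) until the cumulative area
    share reaches the target; returns the set and the achieved share."""
    if target <= 0.0:
        return set(), 0.0
    order = rng.permutation(len(depts))
    total = float(areas.sum())
    chosen: set[str] = set()
    acc = 0.0
    for i in order:
        if acc / total >= target:
            break
        chosen.add(depts[i])
        acc += float(areas[i])
    return chosen, acc / total


def generate_panel(scn: Scenario) -> tuple[YieldPanel, GroundTruth]:
    """Build the panel and its ground truth from a scenario.

    Yields are trend x war-factor + skew-normal noise with
    ``sd = alpha * level**beta``; production is ``yield * area`` so the
    panel's derivation invariant holds; missingness and outlier
    injection are applied last.
    """
    rng = np.random.default_rng(scn.seed)
    y_lo, y_hi = scn.years
    years = np.arange(y_lo, y_hi + 1)
    T = len(years)
    depts = [f"D{i + 1:03d}" for i in range(scn.n_departments)]
    dept_factor = np.exp(
        rng.uniform(-scn.dept_spread, scn.dept_spread, size=scn.n_departments)
    )
    shape, sn_m, sn_s = skewnorm_shape(scn.skewness)

    war, inwar = _war_profile(years, scn.war_periods)
    p_missing = np.where(inwar, scn.war_missing_rate, scn.missing_rate)

    truth = GroundTruth(
        years=years, trend={}, growth={}, stagnating={}, onset={},
        outliers=pd.DataFrame(
            columns=["department_id", "crop", "season_type", "year", "rule"]
        ),
        stagnating_area_share={}, taylor_alpha=scn.noise_alpha,
        taylor_beta=scn.noise_beta, skewness_target=scn.skewness,
        driver_targets=dict(scn.driver_targets),
    )
    qc_rules = OutlierRules()
    frames = []
    outlier_rows = []
    for cs in scn.crops:
        areas = np.exp(
            rng.normal(scn.area_log_mean, scn.area_log_sd, size=scn.n_departments)
        )
        stag_set, achieved = _assign_stagnating(
            rng, depts, areas, cs.stagnating_area_share
        )
        truth.stagnating_area_share[cs.crop] = achieved
        bound = DEFAULT_ABSOLUTE_BOUNDS.get(cs.crop, np.inf)
        k_ratio = qc_rules.mean_ratio(cs.crop)
        rule_cycle = 0
        for d_i, dept in enumerate(depts):
            stag = dept in stag_set
            base = _trend_for(cs, years, stag) * dept_factor[d_i]
            level = base * war
            sd = scn.noise_alpha * np.power(level, scn.noise_beta)
            noise = (stats.skewnorm.rvs(shape, size=T, random_state=rng) - sn_m) / sn_s
            y = level + sd * noise
            y = np.maximum(y, 0.01 * base)

            miss = rng.random(T) < p_missing
            y[miss] = np.nan

            # outlier injection, cycling through the three screen rules
            obs_idx = np.flatnonzero(~miss)
            n_out = rng.binomial(len(obs_idx), scn.outlier_rate)
            if n_out > 0:
                pick = sorted(rng.choice(obs_idx, size=n_out, replace=False).tolist())
                # never inject at adjacent years: the jump rule compares
                # neighbours, and two adjacent corruptions could flag
                # each other in unintended ways
                spaced = [pick[0]]
                for i in pick[1:]:
                    if i - spaced[-1] > 1:
                        spaced.append(i)
                series_mean = float(np.nanmean(y))
                median = float(np.nanmedian(y))
                v_high = 1.6 * k_ratio * series_mean
                v_low = series_mean / (1.5 * k_ratio)
                for i in spaced:
                    rule = ("absolute", "mean_ratio", "mean_ratio", "jump")[
                        rule_cycle % 4
                    ]
                    variant_low = bool(rule_cycle % 2)
                    rule_cycle += 1
                    if rule == "absolute" and np.isfinite(bound):
                        y[i] = 1.5 * bound
                    elif rule == "jump":
                        # needs an adjacent small previous observation
                        j = i - 1
                        if j >= 0 and not np.isnan(y[j]) and y[j] <= median:
                            y[i] = 1.25 * qc_rules.jump_ratio * y[j]
                        else:
                            y[i] = v_high
                            rule = "mean_ratio"
                    else:  # mean_ratio, alternating high / low violations
                        succ_ok = (
                            i + 1 >= T
                            or np.isnan(y[i + 1])
                            or y[i + 1] < 0.8 * qc_rules.jump_ratio * v_low
                        )
                        # a low value before a large successor would make
                        # the successor a spurious jump; fall back to high
                        y[i] = v_low if (variant_low and succ_ok) else v_high
                    outlier_rows.append(
                        (dept, cs.crop, cs.season_type, int(years[i]), rule)
                    )

            area_col = np.full(T, areas[d_i])
            prod = y * area_col
            frames.append(
                pd.DataFrame(
                    {
                        "department_id": dept,
                        "crop": cs.crop,
                        "season_type": cs.season_type,
                        "year": years,
                        "area_ha": area_col,
                        "production_t": prod,
                        "yield_t_ha": y,
                    }
                )
            )
            key = (cs.crop, dept)
            truth.trend[key] = base
            truth.growth[key] = _relative_growth(base)
            truth.stagnating[key] = stag
            truth.onset[key] = cs.stagnation_onset if stag else None

    df = pd.concat(frames, ignore_index=True)[list(PANEL_COLUMNS)]
    truth.outliers = pd.DataFrame(
        outlier_rows,
        columns=["department_id", "crop", "season_type", "year", "rule"],
    )
    panel = YieldPanel(df, provenance=f"synthetic(seed={scn.seed})",
                       year_range=scn.years)
    return panel, truth


def generate_drivers(scn: Scenario, truth: GroundTruth) -> list[DriverSeries]:
    """Department-level fertilizer series calibrated to target
    correlations with the yield trend.

    The signal is the department's mean crop trend scaled to tonnes;
    noise variance solves ``corr(signal, signal + eps) = r`` via
    ``var(eps) = var(signal) * (1 - r^2) / r^2`` using the empirical
    signal variance on the driver span.  A target of exactly 1 would
    require zero noise and is rejected by the scenario validator.
    """
    rng = np.random.default_rng(scn.seed + 1_000_003)
    lo, hi = scn.driver_span
    sel = (truth.years >= lo) & (truth.years <= hi)
    yrs = truth.years[sel]
    out: list[DriverSeries] = []
    depts = sorted({d for (_, d) in truth.trend})
    for dept in depts:
        trends = [tr[sel] for (c, d), tr in truth.trend.items() if d == dept]
        signal = 100.0 * np.mean(trends, axis=0)  # tonnes scale
        sig_var = float(np.var(signal))
        for driver, r in scn.driver_targets.items():
            if r <= 0.0:
                vals = np.full_like(signal, signal.mean()) + rng.normal(
                    0.0, np.sqrt(sig_var), size=len(signal)
                )
            else:
                noise_sd = np.sqrt(sig_var * (1.0 - r * r) / (r * r))
                vals = signal + rng.normal(0.0, noise_sd, size=len(signal))
                vals = vals + max(0.0, 3.0 * noise_sd - signal.min())
            vals = np.maximum(vals, 0.0)
            out.append(DriverSeries(dept, driver, yrs.copy(), vals))
    return out


REFERENCE_SEED = 20_1900


def reference_scenario() -> Scenario:
    """Small deterministic scenario behind :func:`reference_fixture`."""
    return Scenario(n_departments=4, outlier_rate=0.03, seed=REFERENCE_SEED)


def reference_fixture() -> tuple[YieldPanel, GroundTruth]:
    """Deterministic 4-department x 3-crop x 117-year panel.

    Contains stagnating and non-stagnating series and at least one
    injected violation of each outlier rule; used throughout the test
    suite and documentation.
    """
    return generate_panel(reference_scenario())
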