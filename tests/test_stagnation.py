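from dataclasses import replace
from itertools import product

import numpy as np
import pandas as pd
import pytest

from conftest import make_panel
from yieldtrends.dlm import DLMParams, TrendFit
from yieldtrends.stagnation import (
    DEFAULT_SCORE_TABLE,
    POSITION_LABELS,
    StagnationConfig,
    area_share_stagnating,
    classify_position,
    compare_group_yields,
    onset_year,
    sensitivity_sweep,
    stagnation_score,
)

INTERVAL = (0.0, 0.005)


def make_fit(years, g, half_width):
    """TrendFit carrying prescribed relative growth and CI half-widths."""
    years = np.asarray(years)
    g = np.asarray(g, float)
    h = np.broadcast_to(np.asarray(half_width, float), g.shape)
    a = np.full_like(g, 5.0)
    return TrendFit(
        years=years, a=a, var_a=np.zeros_like(g), b=g * a,
        var_b=(h * a / 1.6449) ** 2, g=g, g_lo=g - h, g_hi=g + h,
        n_obs=len(years), loglik=0.0, params=DLMParams(1.0, 0.0, 0.0),
    )


def test_position_examples():
    assert classify_position((-0.01, -0.002), -0.005, INTERVAL) == "P1"
    assert classify_position((0.006, 0.02), 0.01, INTERVAL) == "P10"
    assert classify_position((0.001, 0.004), 0.002, INTERVAL) == "P4"


def test_exactly_ten_reachable_positions():
    """Brute-force enumeration over endpoint/point cells: with
    low <= point <= high, exactly the ten labelled combinations occur."""
    probes = {"b": -0.01, "i": 0.002, "a": 0.02}  # one value per cell
    seen = set()
    for lo, pt, hi in product(probes.values(), repeat=3):
        if not (lo <= pt <= hi):
            continue
        seen.add(classify_position((lo, hi), pt, INTERVAL))
    assert seen == set(POSITION_LABELS.values())
    assert len(seen) == 10


def test_scores_monotone_under_downward_shift(rng):
    """Shifting a CI (and its point) downward never lowers the score."""
    for _ in range(200):
        lo = rng.uniform(-0.02, 0.02)
        hi = lo + rng.uniform(0, 0.02)
        pt = rng.uniform(lo, hi)
        shift = rng.uniform(0, 0.02)
        s1 = DEFAULT_SCORE_TABLE[classify_position((lo, hi), pt, INTERVAL)]
        s2 = DEFAULT_SCORE_TABLE[
            classify_position((lo - shift, hi - shift), pt - shift, INTERVAL)
        ]
        assert s2 >= s1


def test_point_outside_ci_rejected():
    with pytest.raises(ValueError):
        classify_position((0.0, 0.001), 0.002, INTERVAL)
    with pytest.raises(ValueError):
        classify_position((0.002, 0.001), 0.0015, INTERVAL)


def test_overall_score_extremes_and_boundary():
    years = np.arange(1997, 2017)
    cfg = StagnationConfig()
    res = stagnation_score(make_fit(years, np.full(20, -0.01), 0.001), cfg)
    assert res.overall == 1.0 and res.likely
    res = stagnation_score(make_fit(years, np.full(20, 0.03), 0.001), cfg)
    assert res.overall == 0.0 and not res.likely
    # half score-1 years, half score-0 years: boundary 0.5 is inclusive
    g = np.where(years < 2007, -0.01, 0.03)
    res = stagnation_score(make_fit(years, g, 0.001), cfg)
    assert res.overall == pytest.approx(0.5) and res.likely


def test_overall_equals_mean_of_per_year_scores(rng):
    years = np.arange(1997, 2017)
    g = rng.uniform(-0.01, 0.03, size=20)
    res = stagnation_score(make_fit(years, g, 0.004))
    assert res.overall == pytest.approx(res.per_year["score"].mean())
    assert 0.0 <= res.overall <= 1.0
    assert res.n_years_scored == 20


def test_degenerate_ci_scores_by_point_only():
    years = np.arange(1997, 2017)
    below = stagnation_score(make_fit(years, np.full(20, 0.004), 0.0))
    above = stagnation_score(make_fit(years, np.full(20, 0.006), 0.0))
    assert below.overall == 1.0 and above.overall == 0.0


def test_no_window_overlap_rejected():
    fit = make_fit(np.arange(1950, 1960), np.full(10, 0.0), 0.001)
    with pytest.raises(ValueError):
        stagnation_score(fit)


def test_onset_rules():
    years = np.arange(1997, 2017)
    cfg = StagnationConfig()
    # already below U at window start -> onset 1997
    assert onset_year(make_fit(years, np.full(20, 0.004), 0.001), cfg) == 1997
    # crossing in 2002
    g = np.where(years < 2002, 0.006, 0.003)
    assert onset_year(make_fit(years, g, 0.001), cfg) == 2002
    # exactly at U every year: strict inequality -> no onset
    assert onset_year(make_fit(years, np.full(20, 0.005), 0.001), cfg) is None


def area_panel(areas, crop="barley"):
    rows = []
    for dept, area in areas.items():
        for year in range(1997, 2017):
            rows.append((dept, crop, "aggregate", year, area, np.nan, 4.0))
    return make_panel(rows)


def result_with(likely):
    return type("R", (), {"likely": likely})()


def test_area_share_weighted_fraction():
    panel = area_panel({"A": 100.0, "B": 300.0})
    results = {"A": result_with(False), "B": result_with(True)}
    assert area_share_stagnating(results, panel, "barley") == pytest.approx(0.75)
    results = {"A": result_with(False), "B": result_with(False)}
    assert area_share_stagnating(results, panel, "barley") == 0.0


def test_area_share_requires_area_data():
    panel = area_panel({})
    with pytest.raises(ValueError):
        area_share_stagnating({"A": result_with(True)}, panel, "barley")


def test_welch_comparison_matches_hand_formula():
    a = [7.1, 6.9, 7.3, 7.0, 6.8]
    b = [5.2, 5.5, 4.9, 5.1, 5.4]
    out = compare_group_yields(a, b)
    ma, mb = np.mean(a), np.mean(b)
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    t_hand = (ma - mb) / np.sqrt(va / 5 + vb / 5)
    assert out["t"] == pytest.approx(t_hand)
    assert out["p"] < 0.05
    assert out["mean_stagnating"] == pytest.approx(ma)


def test_welch_identical_groups_null():
    out = compare_group_yields([5.0, 6.0, 7.0], [5.0, 6.0, 7.0])
    assert out["p"] == pytest.approx(1.0, abs=1e-9)
    assert out["mean_stagnating"] == out["mean_non_stagnating"]


def test_welch_separated_groups():
    out = compare_group_yields([7.0, 7.001, 6.999], [5.0, 5.001, 4.999])
    assert out["mean_stagnating"] - out["mean_non_stagnating"] == pytest.approx(2.0)
    assert out["p"] < 0.05


def test_welch_rejects_tiny_group():
    with pytest.raises(ValueError):
        compare_group_yields([5.0], [4.0, 4.1])


def test_sweep_single_cell_equals_default_run():
    years = np.arange(1997, 2017)
    fits = {"A": make_fit(years, np.full(20, 0.002), 0.001),
            "B": make_fit(years, np.full(20, 0.02), 0.001)}
    panel = area_panel({"A": 100.0, "B": 300.0})
    cfg = StagnationConfig()
    tab = sensitivity_sweep(fits, panel, "barley", [0.0025], [1997], cfg)
    assert len(tab) == 1
    results = {d: stagnation_score(f, cfg) for d, f in fits.items()}
    direct = area_share_stagnating(results, panel, "barley")
    assert tab["area_share"].iloc[0] == pytest.approx(direct)


def test_sweep_grid_cardinality_and_monotonicity():
    years = np.arange(1997, 2017)
    rng = np.random.default_rng(3)
    fits = {f"D{i}": make_fit(years, rng.uniform(-0.01, 0.02, 20), 0.004)
            for i in range(6)}
    panel = area_panel({f"D{i}": 100.0 for i in range(6)})
    tab = sensitivity_sweep(
        fits, panel, "barley", [0.002, 0.0025, 0.004], [1997, 2000, 2003]
    )
    assert len(tab) == 9
    # raising the upper bound U (via the threshold) never lowers a score,
    # hence never lowers the stagnating area share
    for start in (1997, 2000, 2003):
        shares = tab[tab["window_start"] == start].sort_values("threshold")
        assert shares["area_share"].is_monotonic_increasing
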