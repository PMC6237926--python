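import numpy as np
import pytest
from scipy import stats as sps

from conftest import make_panel
from yieldtrends.dlm import DLMParams, TrendFit
from yieldtrends.variability import (
    DecadeStat,
    ResidualSeries,
    cross_crop_residual_correlation,
    cv_category,
    decadal_cv,
    disturbed_decades,
    quantile_trends,
    residual_skewness,
    residuals,
    taylor_power_fit,
)


def fit_with_level(years, a):
    a = np.asarray(a, float)
    z = np.zeros_like(a)
    return TrendFit(years=np.asarray(years), a=a, var_a=z, b=z, var_b=z,
                    g=z, g_lo=z, g_hi=z, n_obs=len(a), loglik=0.0,
                    params=DLMParams(1.0, 0.0, 0.0))


def test_residuals_basic_identities():
    years = np.arange(1950, 1960)
    a = np.linspace(3, 4, 10)
    fit = fit_with_level(years, a)
    r = residuals(years, a.copy(), fit)
    np.testing.assert_allclose(r.values, 0.0)
    r = residuals(years, a + 0.5, fit)
    np.testing.assert_allclose(r.values, 0.5)


def test_residuals_skip_missing_and_check_alignment():
    years = np.arange(1950, 1960)
    a = np.full(10, 3.0)
    fit = fit_with_level(years, a)
    y = a + 1.0
    y[3] = np.nan
    r = residuals(years, y, fit)
    assert len(r) == 9 and 1953 not in r.years
    with pytest.raises(ValueError):
        residuals(np.arange(1940, 1950), y, fit)


def test_cv_category_edges():
    assert cv_category(0.0) == 1
    assert cv_category(0.15) == 2
    assert cv_category(0.25) == 3  # the 20% anchor separates 2 from 3
    assert cv_category(0.35) == 4
    assert cv_category(0.55) == 5


def test_decadal_cv_example_and_scale_invariance():
    years = np.arange(1950, 1960)
    y = np.full(10, 5.0)
    rng = np.random.default_rng(0)
    rv = rng.normal(0, 1, 10)
    rv = (rv - rv.mean()) / rv.std(ddof=1) * 1.25  # SD exactly 1.25
    res = ResidualSeries(years, rv)
    stats_ = decadal_cv("barley", "D1", res, years, y, year_range=(1950, 1959))
    assert len(stats_) == 1
    s = stats_[0]
    assert s.mean_yield == pytest.approx(5.0)
    assert s.sd_resid == pytest.approx(1.25)
    assert s.cv == pytest.approx(0.25)
    assert s.cv_category == 3
    # multiplying yields and residuals by 1000 leaves the CV unchanged
    res_k = ResidualSeries(years, rv * 1000)
    s_k = decadal_cv("barley", "D1", res_k, years, y * 1000,
                     year_range=(1950, 1959))[0]
    assert s_k.cv == pytest.approx(s.cv)


def test_decadal_cv_zero_residuals_is_category_one():
    years = np.arange(1950, 1960)
    res = ResidualSeries(years, np.zeros(10))
    s = decadal_cv("barley", "D1", res, years, np.full(10, 4.0),
                   year_range=(1950, 1959))[0]
    assert s.cv == 0.0 and s.cv_category == 1


def test_decadal_cv_suppresses_thin_decades():
    years = np.array([1950, 1951, 1952, 1953])  # below the 5-obs minimum
    res = ResidualSeries(years, np.zeros(4))
    assert decadal_cv("barley", "D1", res, years, np.full(4, 4.0),
                      year_range=(1950, 1959)) == []


def stat(mean, sd, decade=1950):
    return DecadeStat("c", "d", decade, mean, sd, sd / mean, 1, 10)


def test_taylor_fit_exact_power_law():
    means = np.array([1.0, 2.0, 4.0, 8.0])
    pts = [stat(m, 0.2 * m**0.7) for m in means]
    fit = taylor_power_fit(pts)
    assert fit.slope == pytest.approx(0.7, abs=1e-12)
    assert fit.intercept == pytest.approx(np.log10(0.2), abs=1e-12)
    assert fit.r2 == pytest.approx(1.0)


def test_taylor_fit_insufficient_or_degenerate():
    with pytest.raises(ValueError):
        taylor_power_fit([stat(1, 0.1), stat(2, 0.2)])
    with pytest.raises(ValueError):
        taylor_power_fit([stat(2, 0.1), stat(2, 0.2), stat(2, 0.3)])


def test_taylor_fit_excludes_listed_decades():
    pts = [stat(m, 0.2 * m**0.7, decade=1950 + 10 * i)
           for i, m in enumerate([1.0, 2.0, 4.0, 8.0])]
    pts.append(stat(1.0, 5.0, decade=1910))  # contaminated war decade
    fit = taylor_power_fit(pts, exclude_decades=[1910])
    assert fit.slope == pytest.approx(0.7, abs=1e-12)


def test_disturbed_decades_default_wars():
    assert disturbed_decades() == {1910, 1920, 1930, 1940}


def test_skewness_examples():
    assert residual_skewness([-1.0, 0.0, 1.0]) == pytest.approx(0.0)
    assert residual_skewness([-3.0, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5]) < 0
    with pytest.raises(ValueError):
        residual_skewness([1.0, 1.0, 1.0])
    with pytest.raises(ValueError):
        residual_skewness([1.0, 2.0])


def test_skewness_matches_target_at_large_n(rng):
    """Skew-normal noise calibrated to -0.2 pools to -0.2 at n=1e4."""
    from yieldtrends.synthetic import skewnorm_shape

    a, m, s = skewnorm_shape(-0.2)
    x = (sps.skewnorm.rvs(a, size=10_000, random_state=rng) - m) / s
    assert residual_skewness(x) == pytest.approx(-0.2, abs=0.1)
    assert abs(np.mean(x)) < 0.05 and np.std(x) == pytest.approx(1.0, abs=0.05)


def quantile_panel():
    rows = []
    for i, v in enumerate([2.0, 4.0, 6.0, 8.0, 10.0]):
        rows.append((f"D{i}", "maize", "aggregate", 2000, 10.0, np.nan, v))
    for i in range(100):
        rows.append((f"E{i}", "maize", "aggregate", 2001, 10.0, np.nan, i + 1.0))
    rows.append(("D0", "maize", "aggregate", 2002, 10.0, np.nan, 7.0))
    return make_panel(rows)


def test_quantile_trends_values():
    q = quantile_trends(quantile_panel(), "maize").set_index("year")
    assert q.loc[2000, "q50"] == 6.0
    assert q.loc[2000, "min"] == 2.0 and q.loc[2000, "max"] == 10.0
    # 5% quantile of 1..100 under linear interpolation
    assert q.loc[2001, "q05"] == pytest.approx(5.95)
    # single-department year is kept but flagged degenerate
    assert bool(q.loc[2002, "degenerate"])
    assert q.loc[2002, "min"] == q.loc[2002, "max"] == q.loc[2002, "q50"] == 7.0


def test_quantile_trends_all_equal_year():
    rows = [(f"D{i}", "oats", "aggregate", 2000, 10.0, np.nan, 3.3)
            for i in range(6)]
    q = quantile_trends(make_panel(rows), "oats")
    row = q.iloc[0]
    for col in ("min", "q05", "q25", "q50", "q75", "q95", "max"):
        assert row[col] == pytest.approx(3.3)


def test_cross_crop_correlation_matrix_properties(rng):
    years = np.arange(1950, 2010)
    shared = rng.normal(0, 1, 60)
    series = {
        "a": ResidualSeries(years, 0.8 * shared + rng.normal(0, 0.6, 60)),
        "b": ResidualSeries(years, 0.8 * shared + rng.normal(0, 0.6, 60)),
        "c": ResidualSeries(years, rng.normal(0, 1, 60)),
    }
    tab = cross_crop_residual_correlation(series)
    m = tab.set_index(["crop_a", "crop_b"])
    for x in "abc":
        assert m.loc[(x, x), "r"] == 1.0
    for x, y in (("a", "b"), ("a", "c"), ("b", "c")):
        assert m.loc[(x, y), "r"] == pytest.approx(m.loc[(y, x), "r"])
        assert -1.0 <= m.loc[(x, y), "r"] <= 1.0
    # shared-shock construction: corr = 0.64/(0.64+0.36) = 0.64
    assert m.loc[("a", "b"), "r"] == pytest.approx(0.64, abs=0.2)
    assert m.loc[("a", "b"), "p"] < 0.05


def test_cross_crop_correlation_short_overlap_not_assessable():
    series = {
        "a": ResidualSeries(np.arange(1950, 1956), np.ones(6)),
        "b": ResidualSeries(np.arange(1953, 1959), np.ones(6)),
    }
    tab = cross_crop_residual_correlation(series)
    row = tab.set_index(["crop_a", "crop_b"]).loc[("a", "b")]
    assert np.isnan(row["r"]) and not row["significant"]


def test_independent_series_rarely_significant():
    hits = 0
    for seed in range(20):
        r = np.random.default_rng(seed)
        years = np.arange(1900, 2000)
        series = {
            "a": ResidualSeries(years, r.normal(0, 1, 100)),
            "b": ResidualSeries(years, r.normal(0, 1, 100)),
        }
        tab = cross_crop_residual_correlation(series).set_index(
            ["crop_a", "crop_b"])
        if tab.loc[("a", "b"), "p"] < 0.05:
            hits += 1
    assert hits <= 2  # ~5% false positive rate
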