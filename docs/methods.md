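# Methods

`yieldtrends` implements a century-scale analysis of subnational crop-yield
panels: trend and growth-rate estimation with a linear Gaussian state-space
model, equivalence-test scoring of recent growth to detect yield stagnation,
inter-annual variability analytics, era-wise clustering of departments, and
driver correlations. Because long historical panels of this kind are only
partially public, the package ships a synthetic-panel generator that emulates
their statistical structure with known ground truth, so every stage is
testable end to end.

## Data model and quality screen

A panel is a long table keyed by `(department_id, crop, season_type, year)`
with harvested area (ha), production (t; hl for wine) and yield (t/ha; hl/ha
for wine). Yields are always recomputed as production/area — printed yields
in historical yearbooks are unreliable — and are missing wherever area is
zero or an input is absent. Boundary changes are harmonized by copying
pre-split yields to successor departments (areas divided equally by default;
configurable) and by pooling pre-merge constituents into one counterfactual
unit with summed area and production.

Three screening rules flag annotation errors: an absolute per-crop upper
bound (10 t/ha for wheat and barley, 100 for sugar beet, 15 for maize, 8 for
oats, 60 for potatoes, 5 for rapeseed and sunflower, 200 hl/ha for wine); a
value more than k times above or below the long-term mean of its own series
(k = 5, with maize 10 and oats/soft wheat 6); and a more-than-20-fold
increase over the immediately preceding calendar year (gaps disable the
rule; decreases are not flagged by default). The long-term mean includes the
candidate value and the screen is a single pass — flagged values are masked
to missing, never corrected, to avoid imputation bias.

## Trend model

The local linear trend model is

    Y_t = a_t + eps_t,            eps_t ~ N(0, sigma2_eps)
    (a_t, b_t)' = G (a_{t-1}, b_{t-1})' + tau_{t-1},
    G = [[1, 1], [0, 1]],         tau ~ N(0, diag(sigma2_a, sigma2_b))

with level `a_t` (yield units) and annual growth `b_t` (yield units per
year). The three disturbance variances are estimated by maximum likelihood
using the prediction-error decomposition of the Kalman filter; smoothed
states and variances come from the fixed-interval (RTS) smoother. Missing
years undergo the time update only and add nothing to the likelihood.
Relative growth is `g_t = b_t / a_t` with a 90% band
`(b_t ± 1.6449 sqrt(var_b_t)) / a_t`; the band ignores uncertainty in `a_t`
(a full delta-method band is a configurable alternative). Years with a
non-positive smoothed level have an undefined rate (NaN) and are skipped by
downstream scoring. Series with fewer than 30 observations are refused and
recorded as not estimated.

Numerical choices: initialization is a proper near-diffuse prior with mean
(first non-missing observation, 0) and variance 1e7 per component (squared
yield units) — standard, and avoids exact-diffuse machinery; the optimizer
works on log-variances (L-BFGS-B, objective tolerance 1e-10) from five
deterministic starts spanning signal-to-noise ratios 1e-2..1e2 of the
differenced-series variance, keeping the best likelihood, because the
variance likelihood of this model is prone to multimodality. The likelihood
recursion is written in scalar form (the state is 2-dimensional), which
makes a 117-year fit run in ~0.2 s.

## Stagnation scoring

A series stagnates over the test window (1997–2016) if its relative growth
predominantly stays inside the stagnation interval [L, U] = [0, 0.5%]/yr,
centred on the 0.25%/yr detection threshold. Each window year is scored by
the position of the 90% CI of `g_t` relative to [L, U]: each CI endpoint
falls below L (strictly), inside [L, U] (inclusive), or above U (strictly),
and where the CI straddles a bound the point estimate's cell disambiguates
— exactly ten reachable positions. The default per-position scores express
confidence that true growth lies below U (1.0 when the CI is at or below
the interval; 0.75/0.5/0.25 grading the straddling cases by the point
estimate; 0.0 when wholly above). This table is a reconstruction — the
original per-position assignments are not published in machine-readable
form — and is fully configurable; it is monotone, so shifting a CI downward
never lowers a score. The overall score is the mean over scored window
years; a series is "likely stagnating" at overall ≥ 0.5 (inclusive), and
the onset year is the first window year with `g_t` strictly below U (the
window start therefore caps how early an onset can be detected). Area
shares weight each assessed department by its mean area over window years
with data. Group comparisons of mean yields use Welch's two-sided t-test
(no test is prescribed by the source analysis; Welch avoids the equal-
variance assumption).

## Variability analytics

Residuals are observed yields minus the smoothed level, at observed years
only. The decadal CV is the decade SD of residuals (n−1 denominator) over
the decade mean of raw yields, computed on calendar decades (1900–1909, …,
2010–2016 truncated) with at least 5 observations; categories are
{0–10, 10–20, 20–30, 30–40, >40}%, anchored at the 20% boundary between
"low" and "moderate-to-high" variability. Mean–variance scaling is an OLS
fit of log10(SD) on log10(mean) across decade-by-department points (the
Taylor power law); skewness is the adjusted Fisher–Pearson sample
estimator; cross-department quantiles use linear interpolation; cross-crop
synchrony is the Pearson correlation of nationally aggregated residual
series (mean and 5%/95% percentile series) on each pair's maximal common
span, requiring ≥ 10 common years.

War-disturbed decades (any decade touching 1914–18 or 1939–45 or their
three recovery years) are excluded from the Taylor fit, though they remain
in the CV tables. The wartime level shifts are systematic trend
disturbances, not inter-annual noise; the trend model tracks them
imperfectly, and the tracking error inflates decade residual SDs exactly at
low decade means, biasing the fitted exponent downward (≈0.48 including
them vs ≈0.66 excluding them when the generating exponent is 0.7).

## Aggregation and clustering

National series are area-weighted means across departments reporting both
yield and area in a year. Decadal growth categories bin each series'
decade-mean relative growth at (−∞,0], (0,0.25%], (0.25%,1%], (1%,3%],
(3%,∞) per year — the stagnation threshold sits on a bin edge — with
counts normalized per decade; wine is excluded by default because its
yields are administratively capped. The small-area sensitivity filter
drops, per crop, departments whose long-term mean area falls below the 10%
quantile of mean areas.

Departments are clustered within four eras (1900–1929, 1930–1959,
1960–1989, 1990–2016) on era-mean yields (≥ 5 observed years), after
trimming the ceil(1%) smallest and largest values (ties broken by
department ID). UPGMA (unweighted average linkage, Euclidean distance on
the scalar means, scipy implementation) builds the dendrogram; the cut k
maximizes the Calinski–Harabasz index CH(k) = [B/(k−1)]/[W/(n−k)] by
exhaustive evaluation, and labels are canonicalized by ascending cluster
mean. The default candidate range is 2..min(10, n/4): for scalar data CH
diverges as clusters shrink toward singletons (W → 0), so candidates are
capped at a minimum mean cluster size of 4; at the ~96-department scale
this coincides with a plain cap of 10. All-identical values are reported
as a single degenerate cluster.

## Drivers

Driver series (mineral N, P2O5, K2O totals in tonnes, 1946–2013; optional
national irrigated area) are department-level, not crop-specific — a limit
on interpretation that the data model makes explicit. Correlations come in
two modes: `raw` correlates levels on the common span (shared long-run
movement), `detrended` removes a smoothed trend from each series first and
correlates residuals (inter-annual co-variation, robust against spurious
shared trends). Summaries report the unweighted mean r across departments
and the share significant at p < 0.05.

## Synthetic panel generator

The generator is the package's study-conditions module: its defaults define
the data regime the tests and verification runs probe.

* **Trend.** Per crop and department, a logistic curve `y0 + (ymax −
  y0)/(1 + exp(−k (t − t0)))` scaled by a department factor
  exp(U(−0.14, 0.14)). Stagnating departments follow a mid-century
  logistic (midpoint 1958, rate 0.09/yr, ~4-fold growth) frozen at its
  value in the onset year (1997) — growth exactly zero afterwards, the
  cleanest testable definition. Growing departments follow a late-midpoint
  logistic (midpoint 2000, rate 0.06/yr) whose relative growth stays above
  ~1%/yr through 2016. Stagnating departments are drawn (in random order)
  until their cumulative area reaches the crop's target share; the achieved
  share is recorded as ground truth.
* **Noise.** Skew-normal, mean 0, SD = alpha · level^beta with alpha = 0.08
  and beta = 0.7, shape solved from the target skewness (−0.2) by the
  moment formula. These values give recent CVs of 5–8%, matching the
  dominance of the lowest CV categories in recent decades of real panels;
  beta < 1 makes the relative variability fall as yields grow.
* **Wars.** Multiplicative dips with floor 0.7 over 1914–18 and 1939–45,
  half-depth in the first war year and a three-year linear recovery —
  wartime collapse and recovery of production were gradual, not stepwise.
  War years are additionally missing with probability 0.7 (against a 0.05
  baseline), reflecting wartime census gaps. Both features matter
  statistically: hard level steps at realistic noise levels force the
  variance MLE to inflate sigma2_a, after which the smoother tracks noise
  everywhere and the recoverable residual structure (skewness, Taylor
  exponent) is destroyed.
* **Corruption.** ~2% of observed values are replaced by injected
  outliers cycling through the three screen rules (absolute: 1.5× the
  crop bound; ratio: 1.6k× above or /(1.5k) below the series mean; jump:
  25× an adjacent small predecessor), spaced so corruptions never sit in
  adjacent years and placed so they cause no collateral flags — the
  screen's recall and precision against the injection list are therefore
  exact by construction on the reference fixture.
* **Drivers.** Fertilizer = 100 × (department mean trend) + Gaussian noise
  with variance sigma_s^2 (1 − r^2)/r^2, so the signal–driver correlation
  hits the target r (N: 0.72, K2O: 0.34, P2O5: 0) on the 1946–2013 span;
  a target of exactly 1 is rejected.

All randomness derives from the single scenario seed; identical scenarios
are bit-identical. `reference_fixture()` is a pinned 4-department ×
3-crop × 117-year panel used across tests and docs.

What the generator does **not** emulate: real geography and spatial
autocorrelation, climate forcing, spring/winter area migration, policy
shocks other than wars, and measurement-error structure beyond the three
injected outlier types. Passing tests therefore demonstrate that the
pipeline recovers the structure it assumes, not that real data satisfy
those assumptions.

## Verification, problem sizes and known limits

`scripts/acceptance.py` re-derives every headline quantity from scratch:
oracle agreement of the filter/smoother with direct joint-Gaussian
conditioning (20 short fixtures; the comparison uses an explicit prior
variance of 10 because conditioning a 1e7-scaled covariance directly loses
~9 digits to cancellation); the OLS closed-form limit; variance recovery
and growth-rate RMSE on 50 series of T = 117 simulated at
(0.09, 0.0025, 0.0004); stagnation operating characteristics on 50 frozen
vs 50 growing series; the ten-position enumeration; screen exactness on
the reference fixture; variability mechanics on a 35-department default
scenario (≥ 10⁴ residuals); the UPGMA brute-force oracle on n ≤ 8
fixtures; and end-to-end recovery of a constructed 60% stagnating area
share over 20 seeds of a 12-department scenario, with a small-area-filter
robustness check over 5 seeds. These sizes keep the full run in a few
minutes on one CPU.

Known limitation: the share of series whose decadal CV is strictly lower
in 2010–2016 than in 1900–1909 plateaus near 85–90%, not higher. With
exponent 0.7 and four-fold mean growth the population CV ratio between
those decades is 4^0.3 ≈ 1.5, while a decade SD estimated from ≤ 10
observations carries log-scale sampling noise of ≈ 0.25–0.31; the
per-series decline probability is then Φ(ln 1.5 / 0.40) ≈ 0.85. A
universal strict decline holds for the population CV (and for the
noiseless generator limit) but not for its 10-observation estimate.
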