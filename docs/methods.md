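# Methods

This note documents the statistical procedures implemented in `aridaq`,
the assumptions behind them, the defaults and why, and what the synthetic
data generator does and does not emulate.

## Aggregation of hourly monitoring data

Hourly station records (local civil time, days as [00:00, 24:00)) are
aggregated without any gap-filling: missing hours are simply removed.
A 24-h mean is valid with ≥ 20 valid hours — the standard completeness
convention for 24-h statistics. The ozone evaluation statistic is the
daily maximum 8-h rolling mean over the 17 windows ending 08:00–24:00; a
window is valid with ≥ 6 of 8 hours, the day with ≥ 14 of 17 windows.
City-scope values are unweighted means over stations' valid daily values,
matching the practice of averaging a city's evaluation sites without
weights. Annual percentiles (CO 95th of daily means, O₃-8h 90th of daily
maxima) use the nearest-rank definition, rank = ⌈p·n⌉ on the ascending
sorted series: deterministic, and always an observed value. Some
assessments use the 95th percentile for ozone instead of the 90th; the
percentile is a parameter (`o3_percentile`), defaulting to 90, the
convention of annual comparison tables.

## IAQI, AQI and levels

Breakpoint tables (HJ 633-2012, 24-h averaging; O₃ as the daily max 8-h
mean) ship as versioned YAML so a different regulatory edition can be
swapped without code changes. The piecewise-linear sub-index is rounded
*up* to an integer, the regulation's convention. O₃-8h is defined only up
to 800 μg/m³; anything above any table's top node is flagged
beyond-index and reported as 500. AQI level bands nominally leave the
boundary values 50/100/150/200/300 unassigned; they are assigned to the
lower band here, which is the only reading under which "excellent or
good" compliance tallies come out as printed in published assessments.
Ties for the maximum IAQI report every tied pollutant as primary.
Seasons are the meteorological ones (Mar–May spring, …, Dec–Feb winter).

## Dust-day screening and deduction

The screening rule (an hour with PM₁₀ ≥ 150 μg/m³ and PM₂.₅/PM₁₀ ≤ 0.30,
relaxed to 0.40 in winter) encodes that mineral dust is coarse: dust
transport produces high PM₁₀ with a low fine fraction, while winter
combustion haze raises both. "Winter" is taken as Dec–Feb. Ratios are
computed per hour at city scope, only where both channels are valid and
PM₁₀ > 0. Deduction eligibility ("more than 600 μg/m³ for 2 h") is read
as ≥ 2 *consecutive* hours above 600. Deduction is implemented as
exclusion of flagged days from the annual PM₁₀ mean — the one convention
that reproduces the published arithmetic (deducted mean 72, increment 5,
rate 5/77 = 6.5%). The contribution to the comprehensive index is
computed from the with/without-dust indices actually supplied, not from
increment/limit shortcuts.

## Comprehensive index and year-on-year table

The comprehensive pollution index is the sum of the six statistic/limit
ratios against the Grade-II limits. It is linear in each statistic, so a
sub-index is exactly the amount the index drops if that pollutant were
absent. Percent changes are rounded half-away-from-zero at one decimal
(two for the index row, matching comparison-table practice). Because
published inputs are themselves rounded to integers, an index recomputed
from them can differ from the published value by up to ±0.02.

## Trend testing and correlation analyses

The Spearman statistic is computed from average ranks (ties allowed) with
the rank-difference formula and compared against the packaged two-tailed
critical values (α = 0.05 table: n = 6 → 0.886; an α = 0.01 table is also
shipped). Constant series have no defined rank trend and raise. Pearson
matrices carry two-sided significance marks (`*` p < 0.05, `**` p < 0.01)
computed per pair via scipy. The heating period is Oct 10 – Apr 10,
boundary days inclusive; the heating-split analysis pairs the k-th valid
day of each period (truncated to the shorter one) and reports Pearson r
with R² = r². Correlation analyses of pollutant–meteorology structure are
intended for monthly aggregates; daily series carry too much weather noise
for the published magnitudes.

## Grey relational analysis

Implemented exactly as the classical deng-style formulation: initial-image
normalization (so degrees are invariant to uniform rescaling of any raw
sequence), two-level extremes over all comparison sequences jointly, and
equal-weight averaging of coefficients over time. ξ defaults to 0.5, the
conventional compromise between discrimination and stability; it is a
parameter. The degenerate case M = 0 (every comparison identical to the
reference) defines all coefficients as 1. Missing values are disallowed
rather than guessed.

## GM(1,1)

Parameters (a, u) solve the least-squares problem on the grey difference
equation x⁰(k) + a·z¹(k) = u, k = 2..n, with background values
z¹(k) = (x¹(k) + x¹(k−1))/2. Restoration and forecasting use the
*discrete-consistent* recursion

    x̂⁰(k) = (u − a·x̂¹(k−1)) / (1 + a/2),   x̂¹(k) = x̂¹(k−1) + x̂⁰(k),

with x̂⁰(1) = x⁰(1). This is a deliberate design choice over the
continuous exponential time response (available as `time_response()`):
the discrete form is exactly consistent with the estimating equation, so
any geometric series (ratio q = (1−a/2)/(1+a/2)) is fitted with zero
residuals, refitting on fitted values is an identity, and parameters of
series generated from the model's own law are recovered to machine
precision — properties the exponential restoration only approximates.
Positive a means decline, negative a growth; the sign of a fixes forecast
monotonicity for positive series.

The posterior-variance test uses population (divide-by-n) standard
deviations: S₁ of the original series, S₂ of the residuals (k = 2..n);
c = S₂/S₁ and p = fraction of residuals within 0.6745·S₁ of their mean.
Grades: 1 when p ≥ 0.95 and c ≤ 0.35; 2 when p ≥ 0.80 and c ≤ 0.50; 3
when p ≥ 0.70 and c ≤ 0.65; else 4 — the conventional grey-theory
thresholds, taking the worse of the p- and c-grades. Model validation
reports in-sample per-point relative errors (k = 2..n); a constant input
with vanishing residuals grades 1, with non-vanishing residuals it is
flagged degenerate.

Numerical notes: n ≥ 4 and strictly positive values are required (the
accumulation step assumes monotone x¹); a = −2 makes the restoration
undefined and raises; residual "zero" in the degenerate S₁ = 0 branch is
judged at 1e−10 relative tolerance.

## Synthetic data generator

The generator emulates exactly the features the analyses key on:

* **Seasonality** — a sinusoid on the log scale per pollutant (positivity
  guaranteed; daily spread becomes lognormal-like), winter peak
  (day-of-year 15) for SO₂/NO₂/PM₁₀/PM₂.₅/CO and a late-June peak for O₃.
* **Heating step** — a per-pollutant multiplier over Oct 10 – Apr 10,
  default 2.5 for SO₂ (coal heating) down to 1.0 for O₃.
* **Dust events** — rectangular hourly PM₁₀ spikes (constant over the
  event hours, unambiguous against the screening thresholds) with a
  configured low PM₂.₅/PM₁₀ ratio; the default calendar has 22 events
  clustered in spring and autumn as dust weather clusters at a
  desert-margin city. Overlapping same-day events are merged.
* **Annual indicator series** — generated from the discrete GM(1,1)
  restored-value law with known (a, u) plus optional additive noise, for
  parameter-recovery tests.
* **Meteorology** — a single latent seasonal factor drives monthly met
  variables and pollutants with loadings ±√strength, so empirical
  correlation signs match the configured pattern in expectation and the
  joint correlation is positive definite by construction. Only rank-one
  sign patterns are expressible; others raise. This suffices for the
  observed pattern, in which all combustion pollutants load against the
  same winter factor and ozone loads opposite.

Default levels (PM₁₀ 70, PM₂.₅ 42, NO₂ 31, SO₂ 7 μg/m³, CO 1.0 mg/m³,
O₃ 85 μg/m³; hourly lognormal noise σ = 0.25; 3 stations with σ = 0.08
between-station spread) are chosen as realistic for an arid northern city
with coal heating. One root seed drives independent sub-streams per
generator (numpy `SeedSequence` spawn keys), so adding a generator never
perturbs another and runs are fully deterministic per seed.

What the generator does **not** emulate: atmospheric chemistry and
dispersion, diurnal cycles, spatial station correlation beyond a static
level offset, autocorrelated synoptic weather, or instrument error
structure. Passing tests therefore demonstrate correctness of the
*statistical machinery* under the assumed data structure, not the
field performance of the screening rules on real monitoring archives.
With the default noise level, the dust screening rule fires on a handful
of naturally noisy non-injected days as well — as it would on real data —
so exact round-trip recovery of injected events is asserted in the
noise-free limit only.

## Pipeline problem sizes

The default pipeline configuration runs one synthetic year of hourly data
for 3 stations and 6 pollutants (~158k records), 8-year annual histories
for the trend/GM stages, and 24 months of meteorology; the whole bundle
computes in a few seconds on one core, and the test suite in well under a
minute. These sizes match the scale of the real problem (one city, one
year of hourly data, 6–8 years of annual statistics).

## Known limitations

* Breakpoint and limit tables cover the shipped regulation edition only;
  other jurisdictions' tables can be supplied as config but are untested.
* The Spearman critical-value tables cover n = 4–30 (α = 0.05) and
  n = 6–30 (α = 0.01).
* The heating-split pairing by day-of-period index is one convention;
  analyses pairing by calendar alignment across years need to construct
  their own paired series.
* GM(1,1) is a short-series trend extrapolator: forecasts reflect only
  the continuation of the fitted first-order dynamic and carry no
  uncertainty quantification.
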