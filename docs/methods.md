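# Methods

This note documents the models, rules and numerical choices behind
`respdiv`, the open design decisions that were settled during
implementation, and what the synthetic-data tests do and do not show
about real trial data.

## Season segmentation

Daily weather (site, date, mean/min/max temperature in °C,
precipitation in mm) is segmented per harvest season.  The *season
year* is the calendar year of the growth period and harvests; its fall
hardening lies in the preceding autumn, so the FH search window is
1 August of the previous year through 30 April, and the winter period
bridges the calendar-year boundary.

**Fall hardening (FH).**  Let

    S(d) = Σ_{i = 1 Aug .. d} [ max(0, 5 − tmean_i) − max(0, tmean_i − 5) ]

be the cumulative balance of cold degree-days below 5 °C minus warm
degree-days above 5 °C.  The FH start is the *last* day with S(d) ≤ 0
(within 1e-9 numerical slack — with measured temperatures an exact zero
is a measure-zero event); if S is positive from the first day the start
is 1 August.  The balance is read as the cumulative sum from 1 August,
not a resettable account: the two readings coincide on typical northern
autumns (S dips while the season is warm and crosses zero once as it
cools) and the cumulative one is well defined in every case.  The FH
end is the last day of the first spell of daily minima ≤ −10 °C that
begins on or after the start; a one-day frost is a spell of length one,
and a multi-day first frost ends FH on its *last* day.  Degenerate
cases are flagged, never silently resolved:

* frost occurs only *before* the computed start → span absent, flag
  `fh_degenerate`;
* no frost at all before 30 April → end capped at 30 April with flag
  `fh_no_frost_capped`, so mild-winter seasons still flow through the
  pipeline (FH-based variables are then treated as missing);
* no frost *and* the balance never returns above zero (e.g. a warm
  frost-free series) → span absent with both flags.

**Growth period (GP).**  Starts on the fifth day of the first run of
five consecutive days with tmean > 5 °C (searched from 1 January; a
broken run restarts the count) and ends with the season's last harvest.
If no such spell exists the season is flagged `no_gp_spell`.

**Winter period (WP).**  From the day after FH ends to the day before
GP starts; absent whenever either anchor is absent or the capped FH end
would overlap the GP.

Dates are whole calendar days and all spans are inclusive on both ends.
Missing weather days are never interpolated: a series records its gaps,
and any season whose required window touches a gap is flagged
`incomplete_weather` and excluded from variable estimation.

## Agroclimatic variables

Fourteen variables are computed per *environment unit* — one
site × harvest-year × experiment, because cut dates (and hence the GP
end and all cut-anchored windows) are experiment-specific.  The
registry (`respdiv.variables.VARIABLE_REGISTRY`) is machine-readable:
id, period, window, weather field, threshold and aggregation rule.

| id | definition |
| --- | --- |
| FH_LENGTH | FH length, days |
| FH_COLD5 | Σ max(0, 5 − tmean) over FH, degree-days |
| FH_RAIN | Σ precip over FH ÷ FH length, mm/day |
| WP_WARM0_RATE | Σ max(0, tmean) over WP ÷ WP length |
| WP_STRESS15 | days in WP with tmin ≤ −15 °C |
| GP_TSUM5 | Σ max(0, tmean − 5) over GP |
| GP_TSUM_RATE | GP_TSUM5 ÷ GP length |
| GP_HOT25_CUT1 | days with tmax ≥ 25 °C in [GP start, cut1] |
| GP_HOT25_CUT2 | days with tmax ≥ 25 °C in [cut1+1, cut2] |
| GP_HOT28 | days with tmax ≥ 28 °C in GP |
| GP_POSTCUT_TSUM7 | Σ max(0, tmean) over [cut1+1, cut1+7] |
| GP_RAIN_CUT1 | Σ precip over [GP start, cut1] |
| GP_RAIN_CUT2 | Σ precip over [cut1+1, cut2] |
| GP_POSTCUT_RAIN14 | Σ precip over [cut1+1, cut1+14] |

Interpretation choices, made once and used throughout:

* "days with maximum temperature of 25 °C (28 °C)" counts days
  *reaching at least* the threshold (a strict-equality reading would be
  empty on real data), using tmax; cold-stress days use tmin ≤ −15 °C,
  consistent with the FH-end rule's use of daily minima.
* The WP warm accumulation and the post-cut temperature sum use base
  0 °C (sum of positive daily means).  A base-5 sum over 7 post-cut
  days cannot reach the magnitudes such variables take in published
  category medians (≈ 100–140 degree-days), whereas base 0 with
  mid-summer means around 17 °C does: a constant 17.3 °C week gives
  7 × 17.3 = 121.1.
* Post-cut windows start the day *after* the cut; the first-cut window
  includes the cut day itself (harvest-day weather belongs to primary
  growth).
* A variable whose anchoring span is absent or flagged, or whose trial
  has no second cut, is *missing with a reason* (`fh_absent`,
  `cut2_absent`, `incomplete_weather`, …), never a silent zero, and
  missingness is monotone in the flags.

## Trial data

Observations are annual DM yields (kg DM ha⁻¹ yr⁻¹, the sum of 2–3
cuts) per cultivar × trial × year.  Missing cut dates are imputed from
a linear mixed model of harvest day-of-year on species and cut-number
fixed effects with a site × year random intercept — i.e. from the
harvest dates of the other cultivars at the same site and year.
Predictions are rounded to whole days and clamped inside the observed
harvest range of the site-year.  When the model is degenerate (no
residual variation, as in toy fixtures) it collapses to the group mean
by construction of the fallback chain (site-year × cut mean →
site-year offset → species × cut mean).  A second cut is imputed only
where the site-year demonstrably has second cuts; a site-year with no
observed dates at all cannot donate and its observations are flagged
and excluded from variable estimation.

**Estimation vs reporting.**  All observations (including long-term
control cultivars from earlier decades) enter the model fits — they
stabilize the yield estimates of modern cultivars.  Profiles, max diff
and gap calls are reported only for cultivars tested in the reporting
window (default 2000–2012) with at least 20 usable observations for the
variable at hand, so the reporting set can differ per variable when
missingness differs.

**Tertile categorization** operates on environment units so that the
random term `unit(category)` is well defined: all observations of a
unit share its label.  Units are ranked by the variable's value, tied
values are kept together, and the two cut points are chosen (by
exhaustive search over tie-block boundaries) to minimize the largest
deviation of any category's *observation* count from N/3; ties in the
objective break deterministically toward the lowest boundary
positions.  The reported breakpoints are the largest values in the low
and moderate categories, so a value classifies as low (v ≤ b1),
moderate (b1 < v ≤ b2) or high (v > b2).  A distribution with fewer
than three distinct values cannot be categorized and raises an error.

## The G×E model

Per species × variable, with all three categories present, ≥ 2
cultivars and ≥ 2 units per category:

    y = μ + cultivar_i + category_j + (cultivar × category)_ij
        + u_unit(j) + ε,   u ~ N(0, σ²_unit),  ε ~ N(0, σ²_ε)

* **Estimation** is REML (statsmodels `MixedLM`, maximum 200
  iterations); the package computes the GLS quantities for inference
  itself from the estimated variance components, using the unit-block
  structure of V.  A REML solution on the σ²_unit = 0 boundary is a
  legitimate fit; degenerate variances are clamped (σ²_ε ≥ 1e-10) for
  the GLS step and noted in the fit's warnings.
* **Tests** are marginal (Type-III-style) F tests: sum-to-zero coding
  makes each term's coefficient block the SAS-style marginal
  hypothesis.  Denominator degrees of freedom default to a
  Satterthwaite approximation (Fai–Cornelius for multi-df contrasts,
  with Var(θ̂) from the expected REML information); when that is
  unusable the fallback is containment-style df (units − 3 for the
  between-unit factor E; N − units − within-parameters for G and G×E).
  The original containment method of the SAS analyses is not
  replicated exactly — p-values may differ slightly; the classification
  thresholds, not SAS parity, are the contract, and the df method is
  recorded in the fit.
* **LS-means** are model cell means from the sum-coded design; on
  balanced data with σ²_unit = 0 they equal raw cell means exactly.
  Cultivars absent from some category have inestimable interaction
  cells and are excluded from the fit with a warning (tests run on the
  estimable subspace).
* **max diff** is max_i r_i − min_i r_i over reporting cultivars, where
  r_i = LSmean_i(high) − LSmean_i(low); the printed sign is that of the
  species-level high-minus-low contrast (mean r over all fitted
  cultivars).  This sign convention is a reconstruction — published
  tables print signed values without defining the sign.
* **Gap rule**: gap ⇔ p_E ≤ α_E and p_GxE > α_GxE, with α = 0.05 for
  both by default ("statistically significant" in the source analyses
  is numberless; 0.05 matches their `**` convention and both thresholds
  are configurable).  Significance stars follow the field's scheme:
  `*` 0.10, `**` 0.05, `***` 0.01, `****` 0.001.
* No multiple-testing correction is applied across the 14 variables,
  matching the published analyses.

`respdiv.reference` embeds a published five-species × 14-variable
significance summary (max diff, G×E and E significance) from a Finnish
official-variety-trial analysis whose raw data are not public.  Star
codes enter logic checks as their upper p-bound.  The package's gap
rule applied to that table reproduces the publication's own per-species
counts of significant G×E variables (0, 1, 2, 8, 1 for timothy, meadow
fescue, tall fescue, festulolium, red clover).

## Synthetic data

**Weather**: tmean(d) = mean + amplitude·cos(2π(d − phase)/365.25) +
AR(1) anomaly (coefficient 0.7, innovation SD 3 °C); tmin/tmax are
tmean ∓ 4 °C further spread by half-range noise (SD 1.5 °C), so
tmin ≤ tmean ≤ tmax holds by construction; precipitation is
Bernoulli(0.45) · Gamma(0.8, 4 mm).  The default preset (annual mean
3 °C, amplitude 14 °C, warmest day ≈ 19 July) emulates a northern
maritime-continental climate: winters reliably produce ≤ −10 °C frost
and springs a > 5 °C spell, so ≥ 90 % of years segment cleanly and
median FH lengths fall in the plausible 20–120-day band.  Sub-streams
are derived deterministically per site from the config seed.

**Trials**: the analysis model run forward.  Units get cut schedules
from DOY rules (cut1 ≈ day 165, +45 and +40 day gaps, 4-day jitter),
are segmented against their site's weather, and are assigned the *true*
tertile of a chosen agroclimatic variable (default GP_TSUM5) computed
from that weather — so the pipeline's own segmentation and
categorization are exercised against known truth, not bypassed.
Yields are μ + cultivar + category + interaction + unit + residual with
defaults μ = 7000 kg DM ha⁻¹, σ_unit = 1000, σ_ε = 400 — the unit
component dominates the random variation, as in real multi-environment
forage trials — and planted interactions are an evenly spread set of
cultivar responses with a configurable high-minus-low range.  Every
planted effect is stored in a truth record.

A weather-free twin (`simulate_model_dataset`, categories assigned
directly in equal thirds) serves the calibration and power studies,
where the environmental pathway is not under test and thousands of
replicates are needed; the full weather path is exercised end-to-end by
the pipeline tests.  Statistical checks use 500 null replicates
(type-I error) and 200 replicates per planted effect size
{0, 750, 1500 kg ha⁻¹} at the 6-cultivar × 30-unit design — sizes
chosen to give binomial confidence intervals tight enough to detect
mis-calibration while keeping the default test run short.

**What passing tests do not show.**  The generator has no spatial or
temporal correlation between sites or years beyond the AR(1) day
scale, no snow cover, soil frost or ice encasement (winter-damage
pathways discussed in the agronomy literature but not computed here),
no yield trend, and no realistic trial imbalance (real networks drop
and add cultivars continuously).  Tests therefore validate the
*machinery* — rules, model, inference, accounting — on data with known
structure, not the climatology of any particular station network.

## Known limitations

* The FH balance is cumulative from 1 August; if a real archive was
  processed with a resettable balance, FH starts could differ in
  unusually warm autumns.
* Satterthwaite df with a single variance component can be fragile in
  tiny designs; the containment fallback is then used and noted.
* The imputation model is deliberately simple (species + cut number +
  site-year); it will not capture cultivar-specific harvest timing.
* Categorization balances observation counts, not unit counts; when
  the two conflict the partition follows observations.
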