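# Methods

## Problem and model

The package detects excess weekly search activity relative to a seasonal
historical baseline. The observed quantity is a relative search volume: the
probability that a sampled search matches a query set, scaled by 1e7, with
an unknown denominator, reported weekly (Sunday-start weeks) and drawn
several times per week to average out the API's sampling noise.

The baseline for the aggregated weekly volume y_w is ordinary least squares
on the training years:

    y_w = b0 + b1 * t_w + f(woy_w) + e_w

- `t_w`: date in fractional years since a configurable origin (default the
  first non-missing training week). Fitted values are invariant to the
  origin and to the unit; only the serialized slope coefficient changes, so
  the model file records the unit ("years").
- `f`: restricted cubic spline in the real-valued week of year,
  woy = 1 + (day_of_year - 1)/7 in [1, 54). Knots sit at the 10th/50th/90th
  percentiles of the observed training week-of-year values, using the
  linear-interpolation quantile definition (numpy default, R type 7). Three
  knots total (k = 3), giving two basis columns; with the intercept and
  trend the training design is n x 4. Three knots is the minimal natural
  spline with any curvature; no boundary-knot augmentation is applied.
- The spline is the Harrell truncated-power parameterization normalized by
  (t_k - t_1)^2: C2 everywhere, exactly linear outside the boundary knots.
  Any rank-equivalent natural-spline basis spans the same space, so fits
  and intervals are basis-robust — tested by reproducing random natural
  cubic splines to machine precision, not assumed.
- The spline is deliberately *not* periodic: week 53 and week 1 are not
  constrained to join. This mirrors the conventional analysis of this kind;
  the small December-to-January discontinuity is a known, accepted artifact.
- Plain OLS, no autocorrelation correction. Residual diagnostics (skewness,
  excess kurtosis, lag-1 autocorrelation, D'Agostino-Pearson normality)
  are reported with soft flags (|skew| > 1, |lag-1 ac| > 0.3) but never
  alter the estimator.

Prediction for a target week with design row x0 (built with the *same*
knots and date origin as training) uses the observation-level interval

    x0'b +/- t_{1-a/2, n-p} * s * sqrt(1 + x0'(X'X)^{-1}x0)

with s^2 = RSS/(n-p). Student-t rather than normal quantiles because s is
estimated from ~157 weeks; the leading 1 makes this a prediction (not
confidence) interval, which is what per-week exceedance classification
requires. No simultaneous/family-wise adjustment is made: the design reasons
per week and uses serial runs of above-weeks as the informal multiplicity
argument.

## Exceedance classification

Each target week is flagged `above` / `below` strictly outside the band,
`within` otherwise (ties at a bound count as within — conservative),
`missing` when suppressed. A target year is "notable" when the outside
fraction exceeds 1 - level *and* the outside count exceeds
ceil((1 - level) * n): at level 0.95 over 52 weeks the expected count is
2.6, so 4+ outside weeks are notable. An exact binomial tail probability
P(X >= n_outside), X ~ Bin(n, 1 - level), is attached as descriptive
context only — weekly residuals need not be independent, so it is never a
decision gate. Maximal runs of consecutive above-weeks (missing breaks a
run) and the first above-week date are reported; for an excess with a known
onset, `ExcessReport.first_above_on_or_after` gives the surveillance
detection delay. That anchored definition matters: under exact 95%
calibration a pre-onset false above-flag appears in roughly half of 52-week
target years, so the *overall* first above-week is a poor timing statistic
for an injected excess.

## Synthetic generator

The generator emulates search-API output with the structure the analysis
assumes: weekly mean

    mu_w = baseline_mean + trend_slope * years + amplitude * cos(2*pi*(woy_w - peak_week)/52)
           [+ injected excess]

and observed replicates mu_w + d_w + e_{w,r}, d_w ~ N(0, week_sd^2) shared
by all replicates of a week, e_{w,r} ~ N(0, rep_sd^2) independent. So
Var(weekly mean of n replicates) = week_sd^2 + rep_sd^2/n — verified
against the closed form. Randomness is split into one `SeedSequence`
substream per week, week deviation drawn before replicate deviations, so
changing `n_replicates` never perturbs week-level noise and fixed seeds are
bit-reproducible. Values strictly below `suppression_threshold` become
missing (default threshold 0, i.e. effectively off, since the suppression
bound of real APIs is unpublished); missing weeks are dropped from fitting,
never imputed. Injected excesses support step, linear-ramp and
exponential-decay shapes, any sign.

Week grid: weeks start on the first Sunday on or after the configured start
date. For a 2017-01-01 to 2020-12-31 series this yields exactly 157
training weeks (2017 contains 53 Sundays) and 52 target weeks — the grid
sizes characteristic of this study design.

Preset parameters (child_abuse, child_witnessed_ipv, ipv) encode levels
~82.6 / 59.0 / 82.8, mild negative or flat year-to-year drifts, peak weeks
23 (early June), 50 (December) and 22, and noise SDs ~6.2-6.5 (week) and
2.0 (replicate, 10 replicates). Amplitudes (4.0 / 3.2 / 1.3) were chosen so
the systematic variance share (A^2/2)/(A^2/2 + week_sd^2 + rep_sd^2/10)
roughly matches the adjusted R^2 the baseline attains on the corresponding
real-world series (~15%, ~11%, ~2%). Two realism caveats, accepted
deliberately:

- A single cosine forces the trough exactly 26 weeks after the peak; real
  seasonality can peak in June yet trough in January (not antipodal). The
  cosine is kept because the true seasonal shape is not identifiable from
  published summaries; the spline baseline does not assume a cosine either,
  so the mismatch does not advantage the method under test.
- Gaussian additive noise with a fixed SD ignores any mean-variance
  relationship and serial correlation of real search data. Passing
  calibration tests therefore demonstrates correctness of the statistical
  machinery under its own assumptions, not robustness to real-data
  violations — the residual diagnostics exist to surface the latter.

## Numerical choices

- Quantiles: linear interpolation between order statistics, so the knot
  oracle tests are exact.
- `fit_ols` rejects rank-deficient designs and n < p + 2 rather than
  silently pseudo-inverting; (X'X)^{-1} is stored in the model file so
  bands can be recomputed without the training data.
- Constant-response fits have undefined R^2; adjusted R^2 is reported as
  1.0 for a perfect fit and 0.0 otherwise instead of NaN (keeps model JSON
  valid).
- Report JSON is written with sorted keys; identical config + seed gives
  byte-identical artifacts.
- Policy-event dates (SIP 2020-03-19, EIP 2020-04-17, PUC expiry
  2020-07-31) are plot annotations only and never enter any computation.

## Simulation sizes

Monte-Carlo checks use sizes chosen to keep the default suite fast while
leaving estimator noise well inside the asserted tolerances: 500 replicates
for null calibration and coverage (also the acceptance script's size;
standard error of the outside-percentage ≈ 0.14pp), 200 for detection
power/timing, 250 vs a 20,000-draw Bernoulli oracle for null run lengths,
1000 weeks for the variance decomposition, 100 random instances for the
normal-equations oracle.

## Limitations

- No live search-API client (key-gated); `fetch_search_volumes` documents
  the expected schema for one.
- No GLS/Newey-West or other autocorrelation-robust variants; no model
  selection over knot counts; no periodic splines; no family-wise bands.
- The generator models API sampling error as additive Gaussian noise only,
  with no semantics of search terms or query curation.
- Causal interpretation of policy timing is out of scope; the pipeline
  reports timing relative to annotated dates, nothing more.
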