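# Methods

This note documents the models and procedures implemented in
`growthfalter`, the conventions and numerical choices behind them, what the
synthetic-data generator does and does not emulate, and known limitations.

## Age and measurement conventions

All ages are integers in days internally; a month is 30.4167 days.
Measurements taken at age ≤ 7 days are analysed as birth ("month 0")
measurements; when several exist, the earliest is used after duplicate-age
averaging. A monthly grid assigns each month m ∈ {1..24} the measurement
nearest to m·30.4167 days within a ±14-day window (earlier measurement wins
exact ties). Because the window is narrower than half a month, windows
never overlap and assignment is order-independent. Repeated records of a
child at one age are replaced by their arithmetic mean before any analysis.

LAZ is computed by the LMS transform z = ((x/M)^L − 1)/(L·S), with the
log-form limit at L = 0, interpolating L, M and S linearly in age; daily or
near-daily reference tables make the interpolation error negligible. The
transform is inverted in closed form, and the round trip is exact to well
below 1e-10. Measurements with |LAZ| > 6 are excluded as biologically
implausible; the boundary value itself is kept (the exclusion rule is
stated as strict inequalities). Dropped rows are retained with reasons for
reporting, never silently discarded.

The packaged LMS table (`data/lms_synthetic.csv`) is **synthetic**: a
smooth, monotone median-length curve with a mild Box-Cox power drift,
covering ages 0–740 days for both sexes in the same CSV schema as the WHO
2006 length-for-age tables. It exists so tests and examples run without
downloads; it is *not* the WHO standard, and absolute LAZ values computed
against it are not comparable to published estimates. Real tables are
drop-in replacements. The same applies to the synthetic velocity-percentile
table.

## Episodes and status transitions

Stunting is LAZ < −2 (severe: < −3; the cutoff is a parameter). Exactly −2
is *not* stunted — every definition below treats ≥ −2 as non-stunted.

Incident episodes: a child born stunted has an incident episode at birth
(age 0). Each observed crossing from ≥ −2 at one measurement to < −2 at the
next is an episode, with onset at the age of the below-cutoff measurement.
A child whose first measurement is post-birth (> 7 days) and already below
the cutoff gets an onset imputed at half the age of that first measurement.

Incidence proportion in a half-open age bin: numerator = children whose
first onset falls in the bin; denominator = children never stunted before
the bin start and under observation in the bin (a measurement inside the
bin, or an imputed onset inside it — the latter covers late entrants whose
imputed onset precedes their first measurement's bin). Sampling variance is
binomial, p(1−p)/n. Bins with an empty denominator are flagged and excluded
from pooling.

Status classification uses six mutually exclusive categories that partition
children at every observed month: never stunted (≥ −2 now and at all prior
observed months), newly stunted (< −2 now, never before), still stunted
(< −2 at previous and current), stunting reversal (< −2 previous, ≥ −2
now), stunting relapse (previously stunted, ≥ −2 previous, < −2 now), and
no longer stunted (previously reversed, ≥ −2 at previous and current).
"Previous" means the most recent *observed* prior month — the
minimal-assumption treatment of gaps; a child unobserved at month m simply
contributes nothing there. Relapses are unbounded in number. Status
analyses are intended for cohorts measured at least monthly, and
month-by-month proportions are simple aggregations over observed children
(not random-effects pooled) so the six categories sum to one exactly.
Because the categories encode history, ever-stunted at month m is simply
1 − P(never stunted), and reversed-and-not-currently-stunted is
P(reversal) + P(no longer stunted).

Post-reversal LAZ: for children classified as reversing at an index month
(3, 6, 9, 12), the within-child difference LAZ(follow-up) − LAZ(reversal)
is summarised per cohort (mean, sample variance / n) and pooled as a mean
difference.

## Growth velocity

Velocity over a 3-month interval is (length₂ − length₁)/Δmonths, with
Δmonths computed from the *actual* ages of the two grid measurements, not
the nominal interval bounds — unbiased under schedule jitter. The same
formula on LAZ gives ΔLAZ/month; the actual-age convention is used for both
metrics. Children missing either endpoint (no measurement within ±14 days
of the nominal month) are skipped. Cohort velocity is the unweighted mean
of child velocities with variance s²/n; cm/month is always sex-stratified
(velocity standards are sex-specific). Percentile banding against a
reference table is left-closed: a value exactly at a tabulated percentile
falls in the band starting there.

## Pooling

Two-stage estimation: a statistic with sampling variance per cohort, then
cross-cohort pooling under the random-effects model
y_i = μ + u_i + e_i, u_i ~ N(0, τ²), e_i ~ N(0, v_i).

τ² is estimated by REML: the profile restricted log-likelihood is maximised
in τ² by bounded scalar optimization (Brent) on [0, 10·var(θ)], absolute
tolerance 1e-8, at most 100 iterations. The fit is declared non-converged
when the upper bound is active or the input is degenerate (no spread in θ),
in which case the estimator cascades to maximum likelihood and then to
inverse-variance fixed effects (w_i = 1/v_i); the output records which
estimator succeeded. k = 1 falls through to fixed effects. Confidence
intervals are Wald, μ̂ ± 1.96·se (no Knapp–Hartung adjustment).
Heterogeneity is Higgins' I² = max(0, (Q − (k−1))/Q)·100 from Cochran's Q
under fixed-effects weights — the standard definition, chosen because the
source of the I² is not otherwise pinned down.

Proportions are pooled on the logit scale with v_i = 1/x_i + 1/(n_i − x_i)
and back-transformed afterwards, which constrains intervals to (0, 1).
Cohorts with zero or full counts get a continuity correction of 0.5 added
to both successes and failures (that cohort only) — standard logit-pooling
practice; the correction and the all-boundary fixed-effects fallback are
flagged on the output. τ² remains on the logit scale after
back-transformation.

Country-year covariates are linearly interpolated between the nearest
observed years; outside the observed range, values within 5 years are
extrapolated from a least-squares line through all observed years (≥ 2
required); anything further is reported absent.

## Distribution models

Age-specific LAZ distributions are fitted with the skew-normal
SN(ξ, ω, α) — the simplest skew-elliptical family member; the skew-t is a
possible extension, not implemented, and the family choice is recorded in
the output. The likelihood is maximised by Nelder-Mead in (ξ, log ω, α)
from two starts: a method-of-moments initialisation (slant from sample
skewness) and the nested normal fit (α = 0). Taking the better of the two
guarantees the skew fit never has lower likelihood than the best normal
fit. Samples under 10 observations and optimizer failures fall back to the
normal fit with a flag; constant samples (ω → 0) raise. Moments (mean, SD,
skewness) are derived from the fitted parameters; skew-normal skewness is
bounded by ≈0.9953 in magnitude.

Mean-LAZ-by-age curves use penalized cubic regression splines: a cubic
B-spline basis with interior knots at quantiles of the distinct ages (at
most 10), an *exact* ∫f″² penalty (second derivatives of cubic B-splines
are piecewise linear, so two-point Gauss–Legendre per knot span is exact),
and a smoothing parameter minimising GCV = n·RSS/(n − edf)² over a 49-point
log-spaced grid anchored at tr(XᵀX)/tr(P). The exact derivative penalty was
chosen over coefficient-difference penalties because its null space is
exactly the linear functions: exactly linear data are reproduced at any
smoothing level. Pointwise standard errors come from the sandwich
covariance σ̂²(XᵀX+λP)⁻¹XᵀX(XᵀX+λP)⁻¹; approximate simultaneous 95% bands
widen the Wald band by a max-t multiplier estimated from 1000 parametric
draws of the coefficient vector.

Empirical percentile curves (e.g. 5th/50th/95th LAZ by month) skip ages
with fewer than 20 observations.

## The synthetic-data generator

The generator emulates the study design the pipeline targets: 32 cohorts
(21 monthly, 11 quarterly), region-shifted birth LAZ with South Asia lowest
(region means −1.10/−0.75/−0.55 for South Asia/Africa/Latin America, a 2:1:1
cohort mix), giving ≈13–15% stunting at birth; a mean-LAZ decline of 0.5 z
from birth to month 15 (flat afterwards); cohort and child random
intercepts (SD 0.25 and 0.8); a within-child AR(1) residual (stationary SD
0.6, lag-1 correlation 0.9, so birth LAZ SD is 1.0 in quadrature with the
child effect); measurement error SD 0.3 z; visit-age jitter of ±3 days; and
10% independently missed visits. Quarterly cohorts are thinned from the
same monthly latent law. Defaults were fixed once from that description;
per-analysis scripts scale cohort and child counts, never the distributional
parameters. The default desk-scale size is 150 children per cohort.

Ground truth retained per child: the latent noise-free monthly LAZ path,
the implied first onset month and full six-category status sequence, and
the realized random effects. `truth_summaries` turns these into true
incidence/status/prevalence tables, the targets for recovery tests. With
measurement error, missingness and jitter all zero, pipeline estimates
equal the truth tables exactly — that identity is asserted in the test
suite. A second generator (`simulate_constant_hazard`) makes onset an
absorbing event with a constant monthly hazard h, so 3-month-bin incidence
has the closed form 1 − (1−h)³ for calibration checks. Nominal visit ages
use the ceiling of m·30.4167 so that month m always lies inside the
3-month bin containing m.

What the generator does **not** emulate: informative dropout (missingness
is non-informative Bernoulli), seasonality, secular trends, twin/sibling
correlation, measurement-device digit preference, cohort-specific
measurement schedules beyond monthly/quarterly, and any weight-based
outcome. Passing recovery tests therefore demonstrates correctness of the
*estimators* under the stated model, not robustness to these real-data
features. Measurement error inflates estimated incidence relative to the
latent truth (noise creates spurious boundary crossings); this is a
documented property of threshold-crossing statistics, tested as a
directional check, not corrected.

## Numerical and design notes

- Ties in grid assignment and duplicate handling resolve deterministically
  (earlier measurement wins), so all outputs are order-independent.
- The incidence denominator rule (observation in the bin required) means
  children lost to follow-up before a bin contribute nothing there; the
  alternative — carrying forward at-risk status — was rejected as it
  assumes unobserved non-onset.
- The birth/bin boundary is configurable (birth window default 7 days); a
  2-day convention for the first bin can be obtained via `AnalysisConfig`.
- Degenerate pooling inputs (identical estimates with vanishing variances)
  deterministically exercise the REML → ML → FE cascade; this is how the
  fallback path is tested.
- Problem sizes in the test suite and acceptance script (e.g. 150–500
  children per cohort, 50 replicates for the τ recovery study) are
  desk-scale choices that keep Monte-Carlo standard errors comfortably
  inside the asserted tolerances.

## Limitations

- The packaged growth reference is synthetic; scientific use requires the
  real WHO tables (same schema).
- Wald intervals can undercover when k is small and τ² is large;
  Knapp–Hartung is not implemented.
- No survey-weighted estimation, no gestational-age adjustment, no
  weight-for-length outcomes.
- Status classification with sparse grids uses the nearest prior observed
  month as "previous", which stretches the one-month transition semantics
  when gaps are long; restrict to monthly-measured cohorts for transition
  analyses, as the interface encourages.
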