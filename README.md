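# growthfalter

Longitudinal analysis of early-childhood linear growth faltering.

Cross-sectional surveys can say how many children are stunted, but not
*when* stunting begins, how often it reverses, or how often it comes back.
Answering those questions requires longitudinal cohorts with frequent
anthropometry and an analysis pipeline that handles the awkward parts:
z-score computation against a growth reference, irregular measurement
schedules, incident-episode definitions, state-transition classification,
and pooling estimates across heterogeneous cohorts. `growthfalter`
implements that pipeline for researchers working with multi-cohort infant
length data (ages 0–24 months), together with a seeded synthetic-study
generator so every stage can be validated against known ground truth.

## What it computes

- **LAZ (length-for-age z-scores)** via the LMS method:
  `z = ((x/M)^L − 1)/(L·S)` (or `ln(x/M)/S` when `L = 0`) with linear age
  interpolation of the reference parameters, exact inversion, duplicate-age
  averaging, and exclusion of implausible values (|LAZ| > 6).
- **Incident stunting episodes** (LAZ crossing below −2, or −3 for severe):
  onset at birth for children born stunted, at each observed
  above-to-below crossing, and imputed at the midpoint of birth and first
  measurement for late entrants; **incidence proportions** by 3-month age
  bin among children still at risk.
- **Stunting-status transitions** on a monthly age grid (months are
  30.4167 days; measurements within ±14 days qualify): six mutually
  exclusive categories — never stunted, newly stunted, still stunted,
  stunting reversal, stunting relapse, no longer stunted — plus
  ever/current stunting curves, birth-LAZ stratification, and within-child
  LAZ change after reversal.
- **Linear growth velocity**: within-child change in length (cm) per month
  (and ΔLAZ/month) over 3-month intervals, using actual measurement ages in
  the denominator, with banding against velocity-percentile reference
  tables.
- **Meta-analytic pooling**: per-cohort estimates pooled by a
  random-effects model `y_i = μ + u_i + e_i` with `u_i ~ N(0, τ²)`,
  `e_i ~ N(0, v_i)`, fitted by REML with ML and fixed-effects fallbacks;
  proportions pooled on the logit scale and back-transformed so intervals
  stay inside (0, 1); Higgins' I² heterogeneity; covariate
  interpolation/extrapolation for subgroup work.
- **Distribution modelling**: maximum-likelihood skew-normal fits of
  age-specific LAZ distributions, penalized cubic-spline mean-LAZ curves
  with GCV-selected smoothing, and empirical percentile curves.

A synthetic miniature LMS reference and velocity-percentile table ship with
the package (same CSV schema as the WHO tables, which are drop-in
replacements), so everything runs self-contained.

## Worked example

```python
import growthfalter as gf

# a synthetic 32-cohort study (21 monthly, 11 quarterly) with known truth
measurements, truth = gf.simulate(gf.GeneratorConfig(seed=1))

ref = gf.load_synthetic_reference()
clean = gf.add_laz_column(gf.average_duplicate_ages(measurements.drop(columns=["laz"])), ref)
clean, dropped = gf.filter_plausible(clean)

# incidence of stunting onset from birth to 3 months, pooled across cohorts
inc = gf.incidence_proportion(clean)
first = inc[(inc.lower_months == 0) & ~inc.degenerate]
pooled = gf.pool_proportions_logit(first.n_incident, first.n_at_risk)
print(f"{100*pooled.mu:.1f}% ({100*pooled.ci95[0]:.1f}-{100*pooled.ci95[1]:.1f})",
      pooled.method)

# status dynamics at 15 months among monthly-measured cohorts
monthly = truth.cohorts.query("schedule == 'monthly'").cohort_id
grid = gf.month_grid(clean[clean.cohort_id.isin(monthly)])
ec = gf.ever_and_current_stunting(gf.classify_status(grid)).set_index("month")
print(f"at 15 months: {100*ec.loc[15,'current']:.1f}% stunted, "
      f"{100*ec.loc[15,'ever']:.1f}% ever stunted")
```

prints

```
21.6% (18.2-25.4) REML
at 15 months: 29.2% stunted, 49.4% ever stunted
```

i.e. in this simulated population roughly a fifth of children at risk
become stunted before 3 months of age, and by 15 months about half have
been stunted at some point while ~29% currently are — the pooled estimate
is a REML random-effects mean across the 32 cohorts, with the confidence
interval back-transformed from the logit scale.

The same stages are available as CLI subcommands
(`growthfalter simulate | zscore | episodes | velocity | pool | distfit |
meancurve`), reading and writing tidy CSVs.

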