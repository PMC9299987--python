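# Methods

## Model structure and assumptions

The population is a closed cohort (everyone who ever received OAT during
the study window) represented as a deterministic, linear,
time-inhomogeneous compartmental system.  State is the cross-product of
six opioid-use stages, two engagement classes and four incarceration
strata; the no-use stage carries strata but no engagement label
(canonicalized to the stable class), giving (5×2 + 1)×4 = 44
compartments.

Key structural assumptions:

* **Markov dwell times.**  Calendar-defined windows ("first month on
  OAT", "released < 1 month ago") are exponential stages with mean equal
  to the window length: exit 12/yr for one-month stages, 1.5/yr for
  months 1–9 on OAT (mean 8 further months), 12/11 per year for the
  1–12-month post-release stratum so mean tracked post-release time is
  12 months.
* **Multiplicative hazards.**  Cause-specific mortality is a baseline
  calendar rate times an OAT-stage factor times an incarceration-stratum
  factor.  Relative risks reported pairwise in the mortality literature
  are reproduced exactly in each pairwise contrast; their joint action
  is the standard multiplicative combination.  First-month factors (on
  and off OAT) apply to both causes jointly; the residual months-2–12
  post-release elevation applies to overdose only; in-prison mortality
  is scaled below community levels by multipliers < 1.
* **Mortality trends.**  Baseline overdose and other-cause rates rise
  linearly from their 2001 anchors (floored at zero); a sensitivity
  structure replaces the overdose trend with exponential growth at
  0.11/yr.
* **Treatment continuity across incarceration.**  Arrest and release
  preserve the opioid-use stage; interruption of OAT by imprisonment
  exists only as an explicit counterfactual (on→off at 100/yr inside
  prison), which is also why the baseline represents a prison system
  that provides OAT with post-release linkage.
* **Engagement classes.**  Membership (rapid turnover vs stable) is
  fixed at cohort entry.  People who cease use (no-use state) lose the
  class label; relapse returns them to off-OAT use in the stable class.
  This slightly understates churn among relapsing former rapid-class
  members; at the default mixing proportion the effect on cohort-level
  mortality is negligible because the class label only modulates
  discontinuation rates.
* **Cessation and relapse.**  Long-stayers (9+ months on OAT, or off-OAT
  "rest of time") may cease both OAT and illicit use at a common rate;
  no-use individuals face only other-cause mortality, keep moving
  through incarceration strata at off-OAT rates, and may relapse.

## Calendar conventions

Snapshot series (cohort size, numbers on OAT, incarceration fractions)
are 1-January states.  Window quantities span whole calendar years:
"2001–16" deaths integrate over [2001, 2017), the 18-year person-year
window is [2001, 2019), and the 20-year impact window is [2001, 2021) —
i.e. through the end of calendar 2020.  The calibration window's last
snapshot is 1 January 2018.  Cohort entries are spread uniformly within
each entry year (a constant inflow rate), which matches 1-January
snapshot semantics without injection discontinuities.

## Parameters

Relative risks and the 2001 mortality anchors default to
posterior-style values from the treatment-mortality literature
(overdose RR on OAT in the community 0.174; other-cause 0.374;
first-month-on 2.294; first-month-off 1.782; prison variants 0.173 /
0.466; post-release first-month 4.032 (overdose) and 1.657 (other);
months 2–12 1.161 (overdose only); re-incarceration on OAT 0.818;
μ1(2001) = 0.003/py, μ2(2001) = 0.009/py).

Structural rates (all per person-year) were chosen once so that the
forward model reproduces the published cohort aggregates — mean on-OAT
census 16,886 within a cohort of ~49k ever treated, ~50% OAT coverage
declining from ~62%, 7.3% currently and ~23% past-year incarcerated,
5,045 total and 1,508 overdose deaths over 2001–16 (≈0.9/100 py crude
all-cause mortality), and a flux-weighted mean episode length near 1.7
years:

| parameter | value | role |
|---|---|---|
| discontinuation, rapid class (M1 / 1–9 / 9+) | 4.0 / 2.5 / 0.78 | ~0.6-yr episodes |
| discontinuation, stable class (M1 / 1–9 / 9+) | 0.8 / 0.45 / 0.13 | ~5.4-yr episodes |
| re-enrolment (community / prison) | 0.58 / 1.4 | ~1.8-yr off-OAT gaps; high prison coverage |
| cessation / relapse | 0.02 / 0.05 | slow growth of the no-use pool |
| incarceration (community / post-release) | 0.24 / 0.60 | 7.3% in prison, ~23% past-year |
| release rate | 3.6 | ~3.3-month mean stay (remand-heavy) |
| prison mortality multipliers | 0.5 / 0.5 | in-prison mortality below community |
| mortality slopes (od / other) | 2.5e-4 / 5e-5 per py per yr | observed rising rates |
| p_stable | 0.5 | class mixing at entry |

The entry schedule runs 2001–2017 with mild geometric decay (ratio
0.98) from an initial 2001 population of ~22.5k at 63% initial
coverage; one forward run supplies an exact multiplicative intake
correction so the mean census matches its target (the system is linear
in population mass).

## Calibration

* **Distance.**  Sum over the seven series and observed years of
  squared deviations, each series normalised by the maximum of its
  observed values; years missing from the data are skipped.
* **Priors.**  Wide uniforms for the mortality anchors (0.001–0.05) and
  slopes (0–0.001); lognormals specified by mean and 95% CI for the
  relative-risk block, fitted by quantile matching (location = midpoint
  of the log CI, scale = log-CI width / 2z₀.₉₇₅) and truncated to the CI
  bounds; ±20% uniforms around the reference values for structural
  transition rates (the convention for turning point estimates of
  calibrated transition rates into priors).
* **ABC-SMC.**  Generation 0 samples the priors; each later generation
  resamples ancestors by weight, perturbs each parameter with an
  independent Gaussian kernel reflected at the prior bounds, and accepts
  under a threshold equal to the 75th percentile of the previous
  generation's accepted distances.  Importance weights use the standard
  prior-over-kernel-mixture formula (reflection mass ignored in the
  kernel density — a second-order effect away from the bounds).
  Iteration stops when the median distance improves by < 0.5–1% or the
  generation cap is reached.  The effective sample size is monitored and
  the run aborts if it collapses below 2.
* **Kernel width.**  With ~30 calibrated parameters, a kernel much
  narrower than the particle spread makes each proposal's mixture
  density single-ancestor dominated; the log-weights then fluctuate like
  χ²(p)/2 and the ESS collapses at any affordable particle count
  (measured ESS 1.0–1.8 with a 0.5×sd kernel).  The default kernel is
  therefore 1.5× the weighted standard deviation per parameter, which
  keeps the ESS near a third of the population; the factor is
  configurable.
* **Reproducibility.**  All sampling flows through one seeded generator;
  identical seeds give bitwise-identical particle stores.

Desk-scale problem sizes, chosen as the package defaults for the
acceptance pipeline: 120 particles × ≤16 generations for the main
calibration and 80 × ≤10 for each sensitivity recalibration (the full
study scale would be 1000 particles).  At these sizes the posterior
brackets every generating parameter at 2% observation noise, but
credible intervals are noticeably wider than a 1000-particle run would
give.

## Integration

Classical fixed-step RK4 on the augmented state (occupancy plus
per-compartment cumulative deaths by cause and person-years), with
sub-steps per year set to max(48, 1.1 × fastest total outflow) rounded
to a multiple of 12 so output lands on a monthly grid.  The prison
interruption scenario (rate 100/yr) automatically raises the step count.
Halving the step changes 20-year cumulative deaths by ≪0.1%, and
frozen-coefficient runs agree with matrix-exponential solutions to
1e-8 of cohort size.  Mass balance (initial + entries = alive +
cumulative deaths) is asserted after every run at 1e-6 relative.

## Scenario engine

Counterfactuals are parameter/rate overrides applied per calibrated
particle; baseline and counterfactual share all other inputs.
Percentage averted uses counterfactual deaths as denominator for the
program-removal scenarios (no OAT, no prison OAT) and baseline deaths —
the PAF convention — for risk-removal scenarios, matching how such
tables are normally printed.  The prison program's share of total
program impact is the ratio of deaths averted (prison scenario over
full-program scenario) computed per particle before summarising.
Post-release efficiency metrics divide the extra deaths in the release
strata by the on-OAT person-years missed in those strata.  Life-years
gained are the difference in total person-years alive over the window.
Sensitivity analyses (exponential overdose trend; no relapse) are
recalibrated before impact, since they alter the data-generating
structure; a switch allows re-using baseline posteriors instead.

ANCOVA variance shares are type-II: each parameter's share is the
increase in residual sum of squares when it is dropped from the full
linear model, as a percentage of total outcome variance.  Shares need
not sum to 100 when parameters are correlated in the posterior, and a
noise-free outcome that is exactly linear in one parameter attributes
~98–100% to it (the shortfall is incidental sampling correlation).

## What the synthetic data does and does not emulate

The generator reproduces the *aggregate* summaries of the NSW cohort
(census level and range, coverage, incarceration fractions, death
counts, crude mortality, episode statistics) by construction, and its
targets are forward-model output plus truncated multiplicative Gaussian
noise (default 2%), so calibration-recovery tests certify the inference
machinery, not fidelity to the real registry.  Features deliberately
not emulated: the true yearly entry counts and their incarceration
split (only the aggregate total is published); the actual shape of the
coverage trajectory between its published endpoints; medication-level
(methadone vs buprenorphine) differences; reporting artifacts such as
uncertain treatment end-dates and the out-of-state death adjustment.
Impact percentages depend on how on-OAT exposure is distributed over
calendar time, so the counterfactual results here characterise a cohort
*like* the published one rather than re-estimating the registry itself.

## Numerical choices and degenerate inputs

Proportion series with zero denominators (no deaths in a year) report 0
and are effectively ignored by the distance when the data carry
information there.  PAFs with zero baseline deaths are flagged NaN with
a warning.  Episode statistics freeze hazards at a reference year
(2010) and propagate one entry cohort through the exact one-year matrix
exponential; an OAT state with no exit at all is reported as infinite
duration.  Collinear or constant parameters are dropped from the ANCOVA
with a warning.  Weighted quantiles use the linear-interpolation
convention that reduces exactly to `numpy.quantile` under equal
weights.

## Known limitations

* The two-class engagement mixture and the single cessation/relapse
  loop are coarse summaries of real engagement heterogeneity; the
  flux-weighted episode duration (~1.5 y over the observed follow-up)
  sits slightly below the registry's 1.74 y.
* ABC posteriors at 120 particles retain prior-shaped tails for weakly
  identified parameters (e.g. the other-cause mortality slope), which
  propagates into wider and mildly shifted impact intervals than the
  full-scale study would show.
* No age structure, no medication or dose effects, no infectious-disease
  co-benefits, no non-fatal overdose.
* The importance-weight formula ignores kernel reflection mass near
  prior bounds; parameters piled against a bound would be mildly
  misweighted.
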