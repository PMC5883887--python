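# Methods

This note documents the statistical procedures implemented in `dthazard`,
the design of the synthetic cohort generator, the numerical choices, and the
limitations a user should keep in mind when interpreting results.

## Discrete-time hazard model

The unit of analysis is the person-month. Subject *i*'s hazard of first
occurrence in month *T* (0-based, month 0 = the survey month) given survival
to *T* is

    logit h_i(T) = alpha_T + x_i(T)' beta

with `alpha_T` one dummy per observed month (reference: the smallest month
present, normally month 0) and `x` drawn from: the monthly administrative
composite `A` (a standardized predicted log-odds that updates every month),
the one-time survey composite `S` (constant within subject), their squares,
their product, and score-by-time interactions in which time is binned
0–12 (reference), 13–24 and 25+ months. A subject contributes rows from
month 0 through the month of first event, attrition, or the administrative
cutoff, whichever comes first; the event month is itself an at-risk row with
the event indicator set (half-open person-period convention, event at
interval end).

Both scores are standardized to weighted mean 0 / variance 1: `A` over
person-month rows (it varies monthly), `S` over subjects, so each subject
keeps one standardized survey value. Whether the original analyses weighted
this standardization is not documented; we standardize with the survey
weights for internal consistency and expose an unweighted path by passing
unit weights.

**Estimation.** Coefficients maximize the survey-weighted Bernoulli
log-likelihood `sum_i w_i [y_i eta_i - log(1 + e^eta_i)]` by Newton–Raphson
with step-halving. Convergence: relative log-likelihood change < 1e-10 or
gradient infinity-norm < 1e-8, at most 100 iterations; non-convergence and
quasi-separated coefficients (|beta| > 15, typically month dummies for
months with zero weighted events) are flagged in the result's diagnostics
rather than silently returned. The fit is cross-checked in the test suite
against an independent general-purpose optimizer and against a GLM fit of
the same objective.

**Design-based inference.** The data come from a single-stage cluster sample
(weekly training cohorts) with non-uniform weights, so sampling variance is
estimated by Taylor linearization: per-row score contributions
`w_i (y_i - mu_i) x_i` are summed within sampling clusters, the cluster sums
are outer-producted (with-replacement assumption) and scaled by the
small-sample factor c/(c-1) (switchable), and the result is wrapped in the
inverse observed information. With one unit per cluster and the factor off,
this reduces to the ordinary heteroskedasticity-robust sandwich. Wald χ²
tests of coefficient blocks use this covariance; confidence intervals are
normal-theory on the log-odds scale and exponentiated to odds-ratio
intervals. Requires at least two clusters.

## The model ladder

Model selection proceeds in two steps over the nested family M1–M11:

* Step 1 (administrative score only): M1 = time only, M2 = +A, M3 = +T·A,
  M4 = +A², M5 = +T·A+A².
* Step 2 (adding the survey score to the selected base `Ba`): M6 = Ba+S,
  M7 = +T·S, M8 = +S², M9 = +T·S+S², M10 = +A·S, M11 = +A·S+T·S.

Each comparison is a design-based Wald test of the added block inside the
larger fit (a difference test in the Wald metric, not a likelihood-ratio
test). The two score main effects (A in step 1, S in step 2) are the primary
hypotheses and are tested at the nominal level `alpha` (default 0.05). The
expansion blocks are screening hypotheses: under the default
`correction="holm"` each step screens its expansion family (T·A, A² /
T·S, S², A·S) by Holm at level `alpha/2`, so the two steps split the
selection error budget and the ladder-wise probability of admitting any
spurious expansion stays near `alpha`. This is a deliberate design choice:
a per-comparison rule at the nominal level (available as
`correction="none"`) admits some spurious expansion in roughly a quarter of
datasets simulated from a purely additive truth, because five null blocks
are each given a 5% chance. The screening choice trades a little power
against weak interactions for a selection that lands on the generating model
~95% of the time in the additive regime.

If the supported expansion set has no named model in the ladder (e.g. S²
together with A·S), the lowest-priority block (S², then A·S) is dropped and
the event is recorded in the run notes.

## Actuarial life table and projected PPV

Follow-up varies from 25 to 44 months (plus attrition), so cumulative risk
is estimated by the classic actuarial life table on monthly intervals:
weighted counts of at-risk `n_j`, events `d_j` and within-interval
withdrawals `c_j` give `q_j = d_j / (n_j - c_j/2)`, survival
`S_j = prod(1-q_k)` and morbid risk `1 - S_j`, reported per 1000 subjects.
Projection is capped at 36 months; the tail beyond that is too thin for a
stable estimate. A Kaplan–Meier variant (no half-interval adjustment) is
exposed for sensitivity analyses but not used in headline outputs. With no
censoring before the horizon the estimator reduces exactly to the weighted
empirical event proportion, which the tests verify. Months-to-occurrence
quantiles are weighted quantiles among observed first occurrences
(lower-value tie-breaking), not survival-function quantiles.

Projected positive predictive value of a subgroup (e.g. a predicted-risk
ventile) is the morbid risk of the life table restricted to that subgroup.

## Ventile evaluation

Respondents are ranked by a per-person risk summary and cut into 20
weighted ventiles (5% of the weighted population each, label 20 = highest
risk; boundary ties to the lower ventile, ties in the score kept in stable
subject order). Reported per model: concentration of risk (percentage of
all observed weighted cases per ventile, 5% expected by chance), observed
PPV (weighted events per 1000 weighted person-months), projected PPV (as
above), top-1/2/3 aggregates, and the proportional improvement
`(best/base - 1) x 100` (to one decimal) of the combined over the
administrative-only model. Published improvement cells that cannot be
reproduced from their own printed inputs (e.g. a printed 16.6 where the
printed pair gives 16.5) are carried in the reference table for completeness
but excluded from recomputation targets.

**Per-person risk summary.** The source analyses rank "respondents" without
stating how monthly predictions become one rank per person. We use the
predicted 36-month cumulative risk `1 - prod_m (1 - h_m)`: observed months
use the fitted hazards; months beyond a subject's observation are
extrapolated with the fitted time effects, carrying the subject's **mean**
observed `A` forward. Carrying the *last* observed `A` (exposed via
`carry="last"`) looks more natural but is outcome-contaminated in
within-sample evaluation: a first event ends observation in a month where
the time-varying score is selectively high, so the carried value encodes
the outcome and systematically flatters models that weight `A` heavily —
in simulation it reverses the expected ordering between the combined and
administrative-only models. A mean-log-odds summary
(`method="mean_log_odds"`) is also available.

## Synthetic cohort generator

The generator produces cohorts with the structure the analysis assumes,
calibrated to the published study conditions; it is the basis of all
simulation tests.

* **Latent structure.** A latent risk `u ~ N(0,1)` drives both scores:
  `S = lambda_S u + sqrt(1-lambda_S²) eps` and
  `A_m = lambda_A(m) u + sqrt(1-lambda_A(m)²) e_m` with `lambda_A(m)`
  linear in month and `e_m` stationary AR(1) (default phi = 0.5). Both
  scores are exactly standard normal marginally and
  `corr(A_m, S) = lambda_S lambda_A(m)`, so rising and falling correlation
  trends are reproduced by the sign of the loading schedule.
* **Events.** Monthly Bernoulli draws from
  `expit(alpha_m + beta_A A_m + beta_S(m) S)`; `alpha_m` carries a negative
  offset (default −1.5) during the first 4 training months, reproducing the
  low early hazard; `beta_S(m) = max(beta_S - decay·m, 0)` allows a survey
  effect that fades with time in service. First event truncates the series.
* **Censoring.** Geometric attrition (default monthly probability
  1 − (16,479/18,838)^(1/12) ≈ 0.0111, matching the observed 12-month
  decline of the male sample) independent of risk, plus an administrative
  cutoff drawn uniformly on 25–44 observable months, mirroring the rolling
  survey window against a fixed records cutoff.
* **Design.** Cluster sizes uniform on 200–300 (weekly training cohorts);
  lognormal weights (log-SD 0.4) normalized to mean 1. The original
  double-weighting construction is not reproduced.
* **Presets.** Three named profiles pin the published targets — incidence
  4.5 / 3.1 / 19.5 per 1000 person-years and median within-month
  correlation .36 / .06 / .26 with the published trend directions:

  | preset | n | lambda_S | lambda_A(0) → lambda_A(43) | beta_A | beta_S | decay |
  |---|---|---|---|---|---|---|
  | physical_perpetration | 18,838 | 0.68 | 0.676 → 0.294 | ln 2.1 | ln 1.6 | 0 |
  | sexual_perpetration | 18,838 | 0.30 | 0.100 → 0.333 | ln 1.4 | ln 2.3 | 0.019 |
  | victimization | 2,952 | 0.60 | 0.567 → 0.267 | ln 1.3 | ln 1.8 | 0 |

  Hazard coefficients are the published best-model odds ratios; the
  loading schedules are chosen so the closed-form correlation series has
  the right level at month 0 and the right median; the sexual-perpetration
  decay reproduces the published pattern of a survey effect weakening from
  OR 2.3 (months 0–12) toward 1.3 (25+).
* **Calibration.** `alpha_base` is set by monotone root-finding so that the
  *expected* incidence matches the target. The expectation integrates the
  hazard over the latent and idiosyncratic score distributions by
  Gauss–Hermite quadrature (41 outer × 21 inner nodes), with survival,
  attrition and the cutoff distribution folded in; months are treated as
  conditionally independent given the latent (the AR(1) correlation of the
  idiosyncratic part is a second-order effect at hazards of 10⁻³–10⁻²).
  At n = 50,000 the realized incidences land within ~2–3% of target.

**What the generator does not emulate:** informative dropout (attrition is
independent of scores and outcome; the source does not model it either),
the double-weighting construction, any dependence between weights and risk,
month-to-month autocorrelation structure beyond AR(1), and of course the
upstream machine-learning models that produce the composite scores — scores
are simulated directly as standardized log-odds composites. Passing tests
therefore demonstrate that the *pipeline* recovers what it should under a
cohort with the published summary structure, not that the published
substantive findings would replicate on real records.

## Operating characteristics verified by simulation

The acceptance suite verifies, at fixed seeds:

* 95% design-based CI coverage of both score effects within [92%, 98%]
  over 500 cohorts of 2,000 subjects from the additive generating model
  (many small clusters, so the with-replacement asymptotics apply);
* type-I error of the survey-score block test within [3.5%, 6.5%] and
  uniformity of its null p-values (KS) over 500 null cohorts;
* the ladder selects exactly M6 in ≥90% of 50 additive-data seeds, and a
  decaying survey effect elevates M7 selection far above its additive-data
  frequency;
* preset calibration at n = 50,000 (incidence within 10%, median
  correlation within ±0.05).

These simulations use a raised baseline hazard (~1% monthly) and a fixed
26–30-month cutoff window so that month-dummy estimates are well identified
at n = 2,000; coverage and size are properties of the estimator, not of a
particular incidence level. The full-scale presets keep the published
incidences.

## Numerical choices and edge cases

* Weighted variance is population-style (`sum w (x-m)² / sum w`).
* Quantile summaries of the correlation series use the lower order
  statistic (numpy `method="lower"`), which reproduces all nine published
  quartile cells of the monthly-correlation table; linear interpolation is
  exposed as an option. The pooled "36+" cell participates in the quartile
  summary (37 values) but is excluded from the month-trend correlation,
  whose month index it lacks.
* Correlation cells with fewer than 3 subjects or zero variance are NaN and
  flagged, never silently dropped.
* Ventile assignment uses the midpoint of each person's weight interval on
  the cumulative-weight scale; with equal weights and distinct scores this
  gives exactly one person per ventile at n = 20.
* Rank-deficient design matrices and single-cluster variance requests raise
  immediately; empty cohorts, zero-event arrays and non-nested model
  comparisons are rejected with named errors.
* All randomness flows from one root seed through per-stage child seeds, so
  any stage can be re-run reproducibly; pipeline reruns are byte-identical.

## Known limitations

* The sandwich variance assumes many clusters; with a handful of large
  clusters (the full preset design has ~75) Wald tests can be mildly
  anticonservative, as is generic for this estimator.
* Extrapolated months in the per-person risk summary reuse fitted month
  effects; months never observed in the fitting data fall back to the
  reference level and are logged.
* The actuarial estimator treats censoring as non-informative; the
  generator satisfies this by construction, real records need not.
* Model selection among M1–M11 does not explore time codings beyond the
  published dummy/bin structure.
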