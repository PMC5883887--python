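# dthazard

Discrete-time survival modelling of rare cohort outcomes with survey-design
inference, actuarial projection, and risk-concentration evaluation — plus a
calibrated synthetic-cohort simulator so the whole analysis can be developed
and tested without access to restricted individual-level data.

## The problem

Large organizations increasingly score their members for the risk of rare
adverse outcomes (violence perpetration or victimization, suicidality) using
prediction models built on administrative records. A one-time intake survey
can capture risk factors administrative data miss — but does adding a
survey-based composite risk score to a monthly-updating administrative
composite actually improve prospective risk targeting, and by how much?

`dthazard` implements the full evaluation pipeline used to answer that
question in new-soldier cohorts:

1. **Person-month hazard models.** Each subject contributes one row per
   month at risk; the probability of first occurrence in month *T* given
   survival to *T* is modelled with a logistic link,

   `logit h_i(T) = alpha_T + beta_A A_i(T) + beta_S S_i + ...`

   where `A` is the standardized monthly administrative score, `S` the
   standardized one-time survey score, `alpha_T` a full set of month
   dummies, with optional quadratics (`A²`, `S²`), a score product (`A·S`)
   and score-by-time interactions (time binned 0–12 / 13–24 / 25+ months).
   Estimation maximizes the survey-weighted Bernoulli likelihood;
   inference is design-based via Taylor-linearization (cluster-sandwich)
   covariance and Wald χ² tests.
2. **A two-step model ladder** (M1–M11): select the best
   administrative-only model, then the best way to add the survey score,
   by design-based Wald tests of each added block.
3. **Actuarial life tables** for cumulative "morbid risk" to 36 months,
   treating within-month withdrawals as at risk for half the month —
   needed because follow-up varies from 25 to 44 months across subjects.
4. **Ventile evaluation**: rank subjects by predicted 36-month risk, cut
   the weighted population into 20 ventiles of 5%, and report concentration
   of risk (% of all observed cases in the top ventiles), observed PPV
   (events per 1000 person-months) and projected PPV (cases per 1000
   subjects at 36 months), plus the proportional improvement of the
   combined model over the administrative-only model.
5. **Score-correlation tracking**: weighted within-month Pearson
   correlation between the two composites, its quartile summary and its
   month trend.
6. **A synthetic cohort generator** whose presets are calibrated to the
   published study conditions: incidences of 4.5 / 3.1 / 19.5 per 1000
   person-years, median within-month score correlations of .36 / .06 / .26
   with rising or falling month trends, training-period hazard suppression,
   attrition matching the published sample decline, weekly training-cluster
   sampling and non-uniform weights.

## Worked example

```python
import dthazard as dt

# a calibrated 4,000-subject cohort of the female victimization profile
config = dt.preset("victimization", n_subjects=4000, seed=21)
cohort = dt.simulate(config)
array = dt.standardize_scores(
    dt.expand_to_person_months(cohort.subjects, cohort.scores)
)

ladder = dt.run_model_ladder(array)
print(ladder.base_name, "->", ladder.selected_name)  # M2 -> M6
print(ladder.selected.summary())
```

```
Discrete-time logistic hazard model  [M6]
terms: T + A + S
person-months: 111719   log-likelihood (weighted): -1266.2061
converged: True in 17 iterations

        term       coef  SE(model)  SE(design)       OR   CI_low  CI_high
       const    -8.3077     0.8935      1.0012    0.000    0.000    0.002
           A     0.2030     0.0773      0.0614    1.225    1.086    1.382
           S     0.6012     0.0784      0.0677    1.824    1.598    2.083
```

The administrative score carries an odds ratio of 1.23 per SD and the survey
score 1.82 per SD in the additive model (the generating values for this
preset are OR 1.3 and 1.8), with design-based confidence intervals from the
cluster sandwich. Ranking subjects by predicted 36-month cumulative risk and
evaluating the top ventile:

```python
fits = {"hads_only": ladder.base, "best": ladder.selected}
report = dt.ventile_report(fits, array, cohort.subjects)
print(report[report.ventile_set == "top1"].to_string(index=False))
```

```
          model ventile_set  concentration_pct  observed_ppv_per_1000pm  projected_ppv_per_1000
      hads_only        top1          11.517469                 4.208903              144.199128
           best        top1          14.884948                 4.985389              168.509042
improvement_pct        top1          29.200000                18.400000               16.900000
```

On this synthetic cohort the top 5% of predicted risk under the combined
model captures 14.9% of all observed victimization cases versus 11.5% under
the administrative-only model — a 29.2% proportional improvement in
concentration of risk; the projected 36-month PPV rises from 144 to 169
cases per 1000 soldiers. (Magnitudes vary across seeds; the direction of
improvement is what is stable.)

The same pipeline is scriptable end to end:

```bash
dthazard report --preset victimization --n-subjects 4000 --seed 21 --outdir out/
```

which writes `correlations.csv`, `model_tests.csv`, `odds_ratios.csv`,
`performance.csv`, `life_table.csv` and a checksummed `manifest.json`;
reruns under the same seed are byte-identical.

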