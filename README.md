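# tmbench — template-matching hospital benchmarking

`tmbench` benchmarks hospital 30-day mortality by **template matching**, a
direct-standardization alternative to regression-based hospital profiling,
for analysts who need to compare hospitals in a multi-hospital system with
strong case-mix variation.  It implements the full method end to end:

1. **Eligibility cascade** — exclude transfers, organ transplants, missing
   and rare principal diagnoses (frequency < 1-in-300), hospitals below the
   3:1 volume floor, and psychiatric/substance-dominant hospitals, with a
   CONSORT-style audit log.
2. **Template selection** — draw 1,000 random samples of 300
   hospitalizations and keep the one whose mean is closest to the system at
   large in Mahalanobis distance,
   `d(x̄_T, x̄) = √((x̄_T − x̄)ᵀ Σ⁻ (x̄_T − x̄))`;
   a tiered variant selects one template per critical-care tier, optionally
   fixing the surgical mix to the tier's median hospital.
3. **Optimal matching** — for each hospital, the minimum-total-distance 1:1
   match of 300 of its hospitalizations to the 300 template cases, with
   *near-exact* constraints (penalized mismatches) and *fine balance*
   (matched category counts must equal the template's exactly), solved
   exactly as an assignment problem with per-category capacities.
4. **Match-quality diagnostics** — the cross-match test (exact
   minimum-weight non-bipartite pairing of the pooled subjects; the number
   of cross-group pairs has an exact permutation null) plus Kruskal–Wallis /
   Pearson chi-square balance tests per matching variable.
5. **Benchmarking** — hospitals ranked by their matched samples' mortality
   (logistic model with sum-to-zero hospital effects, adjusted for
   logit(predicted mortality), clustered on the template case), against the
   conventional hierarchical-regression comparator, with top / median /
   bottom quintile categories and chi-square agreement tests.

A synthetic hospital-system generator with **known true quality effects**
makes every stage testable by parameter recovery, with no restricted data.

## Worked example

```python
from tmbench import (GeneratorConfig, generate_system, fit_risk_model,
                     apply_exclusions, draw_candidates, select_template,
                     MatchSpec, rank_matched, rank_regression, categorize)
from tmbench.matching import match_all_hospitals

config = GeneratorConfig(n_hospitals=12, volume_range=(900, 2500), quality_sd=0.3)
cohort, profiles = generate_system(config, seed=1)
model = fit_risk_model(cohort)
print(f"risk model c-statistic: {model.c_statistic:.3f}")

eligible, log = apply_exclusions(cohort, template_size=300, ratio=3)
print(log.render())

candidates = draw_candidates(eligible, m=300, k=1000, seed=1)
template = select_template(eligible, candidates)
print(f"template Mahalanobis distance: {template.distance:.4f}")

spec = MatchSpec(
    distance_vars=["predicted_mortality", "age", "ed_admission",
                   "nursing_facility", "cm_chf", "cm_chronic_pulm",
                   "cm_paralysis", "cm_renal_failure", "cm_liver",
                   "cm_mets_cancer", "cm_depression"],
    near_exact=["sex", "surgical"],
    fine_balance=["dx_category"])
results = match_all_hospitals(eligible, template.rows(eligible), spec)

report = categorize(rank_matched(results))
print(report.frame.round(3))
```

Output:

```
risk model c-statistic: 0.855
Assessed: 17129 hospitalizations at 12 hospitals
  - transfer from another system hospital: excluded 90 rows (0 hospitals); 17039 rows at 12 hospitals remain
  - organ transplantation: excluded 6 rows (0 hospitals); 17033 rows at 12 hospitals remain
  - missing principal diagnosis: excluded 6 rows (0 hospitals); 17027 rows at 12 hospitals remain
  - rare principal diagnosis: excluded 549 rows (0 hospitals); 16478 rows at 12 hospitals remain
  - hospital volume < 900: excluded 0 rows (0 hospitals); 16478 rows at 12 hospitals remain
  - psychiatric/substance share > 90%: excluded 0 rows (0 hospitals); 16478 rows at 12 hospitals remain
template Mahalanobis distance: 0.1194
             estimate     se  rank category
hospital_id
H001           -0.180  0.278     4   median
H002            0.525  0.246    12   bottom
H003           -0.862  0.372     1      top
...
```

The c-statistic is the risk model's discrimination (probability a death is
ranked above a survivor).  The template distance is how far the selected
template's mean sits from the system mean in covariance-adjusted units.
`estimate` is each hospital's log-odds deviation from the average hospital
on its matched sample (negative = lower mortality = better); `rank` 1 is
best; categories are the top quintile / middle three quintiles / bottom
quintile.  On this synthetic system the matched-sample ranking agrees with
the hierarchical-regression ranking on 8 of 12 hospitals (0.67), and the
true quality effects stored in `profiles` let you check recovery directly.

A command-line interface wraps the same stages
(`tmbench generate | fit-risk | filter | select-template | match |
diagnose | rank | compare | run-all`), driven by a YAML config; `run-all`
writes every artifact (exclusion log, templates, match results, balance
tables, both rankings, agreement tables, and a reproducibility manifest)
into a run directory.

## Layout

```
src/tmbench/
  synthetic.py    multi-hospital cohort generator with true quality effects
  risk.py         predicted-mortality logistic model + c-statistic
  filters.py      eligibility cascade with audit log
  template.py     candidate drawing and Mahalanobis template selection
  matching.py     optimal 1:1 matching with near-exact & fine balance
  diagnostics.py  cross-match test, Kruskal-Wallis / chi-square balance
  benchmark.py    matched-sample and regression rankings, quintiles
  pipeline.py     run configuration and orchestration
  cli.py          command-line interface
docs/methods.md   model and design notes
```
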