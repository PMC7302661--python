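# Methods

`tmbench` implements template matching for benchmarking hospital 30-day
mortality in a multi-hospital system, together with the conventional
regression comparator and a synthetic system generator that makes the whole
pipeline testable against known truth.  This note records the statistical
model behind each stage, the defaults and why they were chosen, the
numerical decisions, and what the synthetic experiments do and do not
demonstrate.

## The benchmarking problem

Indirect standardization (regression benchmarking) compares a hospital's
observed mortality with the mortality a system-wide model predicts for that
hospital's own patients.  When hospitals see very different patients, those
predictions are extrapolations.  Template matching is a form of direct
standardization: fix one representative sample of hospitalizations (the
*template*), select from every hospital the sample most similar to it, and
compare all hospitals on the outcomes of these matched samples.  Every
hospital is then measured against the same yardstick, at the price of
requiring that every hospital actually *has* hospitalizations resembling
the template — which is exactly what strong case-mix variation breaks, and
what the match-quality diagnostics are designed to detect.

## Synthetic hospital system

`synthetic.generate_system` draws, per hospital, a case-mix profile
(mean age, sex mix, race/ethnicity mix, 29 comorbidity prevalences, 7
broad principal-diagnosis category probabilities, surgical /
emergency-department / nursing-facility admission probabilities, and
per-lab mean shifts for 11 admission labs) and a true quality effect — a
log-odds offset added to every admission's 30-day death probability.
Outcomes are Bernoulli draws from a logistic model over the admission
covariates plus that offset, so the hospital quality ordering is known
exactly and every downstream stage has a parameter-recovery target.

Key choices:

* **Heterogeneity is one scale.**  Every hospital-level deviation (additive
  mean-age shift, logit-scale prevalence shifts, log-scale diagnosis-mix
  tilts, lab-mean shifts) is proportional to the `heterogeneity` parameter.
  At 0 all hospitals share one case-mix; at the default 1.0 the
  between-hospital ranges emulate a large integrated system (surgical share
  roughly 1–40%, emergency-department share roughly 2–99%,
  psychiatric/substance share roughly 2–70% across hospitals).
* **Volumes** are log-uniform over the configured range (default 40
  hospitals, 300–3,000 admissions/year), mimicking the right-skew of real
  systems whose volumes span a 50-fold range, at a scale a laptop can
  simulate repeatedly.
* **Labs** are multivariate normal around tier- and diagnosis-shifted means
  with a fixed plausible covariance (BUN–GFR negatively correlated, pH–PaCO2
  negatively correlated, etc.).  Only the rank structure and balance of labs
  matter downstream, so no attempt is made at clinically exact marginals.
* **Fine diagnosis categories** refine each broad category into 8
  subcategories with Zipf-like (exponent 1.6) conditional frequencies, so a
  realistic long tail of rare principal diagnoses exists and the 1-in-300
  rare-diagnosis exclusion has something to bite on.
* **Outcome-model coefficients** (`default_outcome_coefficients`) are
  chosen to give a pooled 30-day mortality near 5% and a risk-model
  c-statistic near 0.83, typical of inpatient mortality models; they are
  invented defaults, not estimates from any dataset, and are fully
  overridable.
* **Determinism.**  One master stream (from the run seed) draws profiles;
  each hospital's rows come from a deterministically spawned substream, so
  identical config+seed reproduces byte-identical tables.

What the generator does **not** emulate: longitudinal structure, missing
data, coded ICD diagnoses, transfers with re-attribution logic (transfers
are simply flagged rows), or hospital practice patterns correlated with
quality.  Passing recovery tests on this generator therefore shows the
machinery is correct and well-powered under known truth, not that real
benchmarking disputes would be settled correctly.

## Risk model

A main-effects logistic regression of 30-day mortality on age, sex,
race/ethnicity, surgical indicator, admission source, broad diagnosis
category, indicators for the 20 most common fine diagnosis categories, 29
comorbidities, and 11 labs.  Estimation is IRLS (tolerance 1e-8, max 100
iterations).  Quasi-separation — detected by non-convergence or runaway
slope estimates (|slope| > 30; the intercept is exempt because it absorbs
raw-scale lab means) — triggers an L2-penalized fallback that is flagged on
the returned model.  Discrimination is the c-statistic computed from
mid-ranks (ties count 1/2), i.e. the normalized Mann–Whitney statistic.

## Eligibility cascade

Rules run in a fixed order: transfers from another system hospital →
organ-transplant admissions → missing principal diagnosis → rare principal
diagnosis (fine-category frequency strictly below 1-in-300 of the rows
remaining after the first three rules; the denominator is configurable
because "remaining eligible" is ambiguous) → hospitals below the
template-size × ratio volume floor (900 for a 300-case template at 3:1) →
hospitals with a psychiatric/substance share strictly above the threshold
(default 0.90).  The log records rows and hospitals removed at each step
and checks conservation; the cascade is idempotent.

## Template selection

Candidates are simple random samples of m=300 rows drawn without
replacement (default 1,000 candidates); the selected template minimizes
the Mahalanobis distance between the candidate mean and the population
mean on a selection roster (default: predicted mortality, observed
mortality, sex, race/ethnicity, surgical indicator, the 7 diagnosis
categories, and 7 major comorbidities).  The population covariance is
estimated from the full eligible cohort and inverted by pseudo-inverse:
one-hot indicator blocks make it near-singular, and the pseudo-inverse
handles the rank deficiency without ad hoc ridge terms.  Zero-variance
columns are dropped with a warning.  Ties break toward the lowest
candidate index, making selection deterministic.

In tiered mode one template is selected per critical-care tier from that
tier's pooled rows.  Optionally the surgical/non-surgical split is fixed
at the tier's median within-hospital surgical proportion
(n_surgical = round(m·p*)); hospitals lacking a ratio:1 pool in either
stratum are flagged ineligible (a (50, 250) split demands 150 surgical and
750 non-surgical rows).

## Matching engine

For each hospital the engine finds the 1:1 assignment of template cases to
hospital rows minimizing total pair distance, where the pair distance is
the Mahalanobis distance on the distance roster (pooled-cohort covariance,
pseudo-inverse) plus a penalty per mismatched near-exact variable.  The
default penalty, (m+1) × the largest base distance in the instance, makes
near-exact agreement lexicographically dominant: if a zero-mismatch
assignment exists, every optimum has zero mismatches.

Fine balance requires the matched sample's category counts to equal the
template's exactly.  Multiple fine-balance variables are enforced on their
cross-classification — the nested-refinement behaviour of layered
fine-balance matching — which implies exact marginal balance of each
variable.  The constrained problem is a min-cost flow; it is solved in its
equivalent assignment form, in which one dummy row per unit of pool
surplus in each category (cost 0 within its category, forbidden elsewhere)
realizes the per-category capacity nodes, and the exact Jonker–Volgenant
solver produces a true optimum.  Consequences verified by the test suite:
reported optima equal exhaustive-search minima; reported fine balance holds
with integer equality; adding a constraint never decreases the total.

Failure modes are explicit, never silent: a pool below ratio × m is
*ineligible*; a counting-infeasible constraint set is *infeasible* with the
binding variable named (the first variable in priority order whose layer
breaks feasibility); an instance above the size budget (default 25M cost
cells) is *non-converged*.  Rank-based robust distances, used by some
matching tools, are a documented extension point and deliberately not the
default: plain Mahalanobis is transparent and directly testable.

## Match-quality diagnostics

**Cross-match test.**  Pool the 300 template cases with a hospital's 300
matched rows, pair all 600 subjects by exact minimum-weight non-bipartite
matching (blossom algorithm) on Mahalanobis distance, and count cross-group
pairs A1.  Few cross pairs mean the groups occupy different covariate
regions.  The null pmf of A1 — all pairings of labels equally likely — has
the closed form

    P(A1 = a) ∝ C(n1,a) C(n2,a) a! M(n1−a) M(n2−a),

with M(m) the number of perfect pairings of m subjects; it is evaluated in
log space and used *exactly at every group size* (it is O(n) and stable at
n = 300, so no normal approximation is needed; the closed form is validated
against full pairing enumeration for n ≤ 6).  The p-value is P(A1 ≤ a1).
Because the null is discrete and A1 has forced parity, the test is
conservative: at n = 20 per group the largest attainable level below a
nominal 0.05 is P(A1 ≤ 4) ≈ 0.0075.  The blossom solver is cubic in the
pooled size, so pipeline-scale tests run on a seeded random subsample of
each group (default 75 per side); the subsampled test is still exact under
its null, at reduced power.  "Poorly matched" means p below a configurable
threshold (default 0.05 — the cutoff is an assumption, not an estimate).

**Balance tests.**  One omnibus test per matching variable across all
hospitals' matched samples: tie-corrected Kruskal–Wallis for continuous
variables, Pearson chi-square (no continuity correction) on the
hospital-by-category table for categorical ones.  "Balanced" means
p ≥ threshold (default 0.05, configurable; also an assumption).  Constant
variables are reported as degenerate-balanced with a warning rather than as
a spurious number.

## Benchmarking models

**Template-matching ranks.**  The stacked matched samples are analysed
with logistic regression: outcome ~ hospital effects (sum-to-zero coding,
so each effect is a deviation from the average hospital) + logit(predicted
mortality).  Each template case indexes one cluster containing its matched
row from every hospital, and standard errors are cluster-robust on that
index — the package's reading of "clustering on the template matched
patient".  A random-intercept-per-template-case formulation gives
essentially identical point estimates of the hospital contrasts; the
fixed-effects-plus-cluster-robust form was chosen because it is exact,
fast enough for hundreds of simulation replicates, and free of
variance-component boundary issues.  A hospital with zero (or all) deaths
makes the MLE non-existent; a weak ridge (λ=1) is then applied and flagged
in the report metadata.  Hospitals are ranked ascending in estimated
effect; ties break by hospital id.

**Regression comparator.**  The conventional hierarchical
(random-intercept per hospital) logistic model on the full eligible
cohort, adjusted for logit(predicted mortality), estimated as two-stage
empirical Bayes: (1) per-hospital log-odds offsets δ_h against the pooled
risk-adjusted model, with a weak N(0, 10²) prior (λ=0.01) that regularizes
all-survivor hospitals; (2) between-hospital variance τ² by
DerSimonian–Laird moments; (3) posterior-mode shrinkage
b_h = τ²/(τ²+se_h²)·(δ_h − μ̂).  Hospitals are ranked on b_h.  This is the
standard empirical-Bayes approximation to the Laplace mixed-model fit and
agrees with it closely away from τ² = 0; at τ̂² = 0 all hospitals shrink
to a common value, which is the correct degenerate behaviour under no true
quality variation.

**Categories and agreement.**  Ranked hospitals are cut into top quintile
/ middle three quintiles / bottom quintile with a ceiling rule
(k = ⌈H/5⌉ top and bottom; 10 hospitals → 2/6/2, 117 → 24/69/24).
Two reports are compared by the Pearson chi-square test on their 3×3
category cross-tabulation, plus the simple fraction of hospitals assigned
the same category.

## Problem sizes in the test and acceptance suites

Simulation-backed checks use sizes chosen to give stable verdicts on one
CPU: solver-optimality on 200 random instances against exhaustive search;
fine balance on 100 constrained instances; the cross-match null validated
by complete enumeration (n ≤ 6) and by 2,000 null replicates at n = 20 per
group; two-hospital separation (quality effects 0 vs +1, homogeneous
case-mix so the estimator, not confounding, is on trial) over 500
replicates; rank recovery on 40-hospital systems (volumes 300–3,000,
quality-effect SD 0.3) over 12 replicates; the heterogeneity contrast
(scale 0.3 vs 1.5) over 10 paired replicates.  `scripts/acceptance.py`
re-runs the same computations at slightly smaller replicate counts and
reports the measured numbers.

## Known limitations

* Strict fine balance either holds exactly or is declared infeasible;
  penalized near-balance (as in some network tools) is not implemented, so
  heterogeneous systems see more outright infeasibility and fewer
  approximately-balanced matches.
* The cross-match subsample trades power for tractability at the default
  600-subject scale.
* The regression comparator's empirical-Bayes variance estimate can hit
  zero in small systems, collapsing all shrunken effects; ranks then fall
  back to hospital-id order and should be read as "no detectable quality
  variation".
* Quality effects in the generator are independent of case-mix; real
  quality–case-mix correlation would make both benchmarking methods look
  better or worse in ways these simulations cannot reveal.
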