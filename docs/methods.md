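# Methods

## Problem and approach

Pulmonary arterial hypertension (PAH) is a rare, progressive pre-capillary
pulmonary vasculopathy whose gold-standard diagnosis requires right heart
catheterization (RHC). Identifying PAH patients inside a large electronic
medical record (EMR) or claims database from *coded data alone* is hard:
ICD-9/10 pulmonary-hypertension codes are imprecise, RHC procedure codes are
shared with other indications, and PAH-specific drugs see off-label use.

`pahphen` implements a staged, machine-learning case-identification
procedure over three administrative vocabularies (ICD diagnosis codes, CPT
procedure codes, medication mentions), together with a synthetic EMR
generator so that every stage is exercisable and testable without access to
any real medical record.

## The feature calculus

Each screened variable `v` (a PH ICD code, an RHC CPT code, or a medication
brand/generic name) is reduced, per patient, to three longitudinal scalars:

* **strength** `s_v` — number of mentions of `v` in the record (same-day
  duplicates each count);
* **persistence** `p_v` — whole days from the first to the last mention
  (`p_v = 0` for a single mention);
* **durability** `d_v = p_v / (T - t_first)` — persistence relative to the
  record length remaining after the first mention, where `T` is the record
  end; `0/0` is defined as 0, so `d_v ∈ [0, 1]`.

Persistence is read as span-of-mentions rather than first-mention-to-record-
end: the discriminating signal for true PAH is *sustained* therapy, and a
span measure distinguishes years of epoprostenol refills from a one-off
sildenafil mention with the same code. The durability denominator excludes
a +1 day so a mention on the final record day scores exactly 0. Brand and
generic names are separate variables by default (Flolan and epoprostenol
accumulate independently, mirroring how pharmacy feeds record them); a
`collapse_aliases` switch pools aliases onto the canonical generic.

## Screening and adjudication

A record is *flagged* when it has at least one event in any of the three
categories; flagged records are ranked by the count of distinct categories
(0–3), ties broken by patient id, and reviewed in rank order up to a
configurable review budget. The review oracle applies the WSPH
pre-capillary rule to RHC hemodynamics: `mPAP >= 25 mmHg`, `PVR >= 3 WU`,
`PCWP <= 15 mmHg`, all inclusive; a record without hemodynamics adjudicates
not-PAH, because the gold standard requires a catheterization and the
classifiers need a binary label. The oracle ignores everything except
hemodynamics — no inter-rater noise, no mixed-etiology judgment calls.

## Classifiers and hyperparameter optimization

Three families are trained at every stage: random forest, XGBoost, and the
elastic net (logistic regression with a mixed L1/L2 penalty behind a
standard scaler; mixing ratio `alpha ∈ [0,1]`, penalty `lambda` log-uniform
`1e-4…1e1`, `C = 1/lambda`). Hyperparameters maximize the mean AUC of
stratified k-fold cross-validation repeated r times (defaults 10 × 3 → 30
fold-level AUC samples, reported as mean with a normal-approximation 95% CI
over the resamples). The optimizer is sequential model-based: a
Gaussian-process surrogate (Matern-5/2 + white noise) over the unit
hypercube with expected-improvement acquisition, seeded and fully
deterministic; default 10 random initial points + 30 guided evaluations.
After tuning, the model is refit on the entire training set.

Default search bounds: RF — 200–1000 trees, max-features fraction
0.05–1.0, min leaf 1–20; XGBoost — learning rate 0.01–0.3, depth 2–8,
50–500 rounds, subsample 0.5–1.0. The classification threshold is 0.5
everywhere and exposed in configuration, since PPV/NPV depend on it.

Feature importance is *permutation* importance — mean AUC drop on held-out
data when one column is shuffled — chosen over impurity importance because
it is comparable across the differently scaled strength / persistence /
durability components.

## The staged pipeline

1. **Development** — screen, rank, adjudicate the top records within the
   review budget, split 70/30 (stratified, per-class floor rounding on the
   test side), train all three families, keep the best test AUC (ties:
   RF > XGBoost > elastic net). This is the Initial Algorithm.
2. **Refinement** — deploy the Initial Algorithm on remaining flagged
   records; adjudicate *only predicted positives*. Confirmed and refuted
   predictions both become labeled data. Predicted negatives are never
   reviewed; the resulting verification bias is a property of the design
   and is documented, not corrected.
3. **Final** — pool both labeled sets, excluding under-18 development
   patients; split 80/20 per class with floor rounding (653 cases + 1041
   non-cases yields exactly 1356 train / 338 test); train all three
   families from scratch (no fitted state carries over); the random forest
   is designated final by default.
4. **Internal validation** — deploy the final model on every patient not
   used for training or tuning (final-test-set members remain deployable,
   since the model never saw them) and aggregate predicted positives: age,
   sex, connective-tissue and congenital-heart-disease comorbidity rates,
   medication-class exposure (ERA, GC stimulator, PDE5 inhibitor,
   prostanoid), and hemodynamic means over those with RHC rows. No
   adjudication occurs — this emulates deployment on a pure claims
   database.

A structural leakage guard asserts that no stage's test ids intersect its
training rows, and the end-to-end run is deterministic under one master
seed (stage seeds are fixed offsets of it).

## The synthetic EMR generator

The generator emulates a de-identified hospital record with five latent
strata, drawn iid per patient:

| stratum | default weight | planted signal |
|---|---|---|
| `true_pah` | 1% | 2 PAH drugs mentioned ~monthly across ~70% of the record, an RHC CPT, repeated PH ICD codes, WSPH-consistent hemodynamics |
| `postcapillary_ph` | 5% | PH ICD codes + RHC CPT, wedge > 15 mmHg, no PAH drugs |
| `offlabel_med_user` | 3% | 1–3 PDE5-inhibitor mentions inside a 60-day window, no PH ICD |
| `code_only` | 3% | 1–2 isolated PH ICD mentions |
| `background` | 88% | filler codes only |

Record spans are Normal(3650, 1500) days floored at 365; time is whole days
from a fixed anchor with no calendar structure, because the feature
calculus needs only day arithmetic. Hemodynamics are rejection-sampled
normals — true-PAH means/SDs mPAP 49.8 ± 13.6, PCWP 11.3 ± 6.1, mRA
10.1 ± 6.0 mmHg, CO 4.8 ± 1.7 L/min — constrained so the true-PAH stratum
satisfies the WSPH rule and every other stratum fails it (post-capillary
additionally requires PCWP > 15). PVR is derived as `(mPAP − PCWP)/CO` and
cardiac index as `CO / 1.9 m²` (a fixed adult body-surface area; no
anthropometric model is carried). A patient's truth label is *defined* as
the WSPH rule applied to their planted hemodynamics, so the adjudication
oracle and the generator can never disagree — a closure that the tests
verify on 10,000 records.

Rejection constraints shift the sampling moments away from the raw normal
parameters (conditioning PCWP ≤ 15 pulls its mean to ≈ 9.0 mmHg);
`truncated_hemodynamic_moments` documents the shift with a brute-force
Monte-Carlo estimate, and calibration/recovery checks compare against those
truncated moments, not the raw ones.

Demographics follow the target phenotype: true-PAH patients are 72% female,
age 52 ± 14, with 33% connective-tissue and 19% congenital-heart-disease
comorbidity markers; other strata 54% female, age 52 ± 21, 2%/1%
comorbidity. Off-label exposure rates among non-cases have no empirical
anchor and are free parameters.

`simulate_persistence_contrast` builds a controlled experiment in which
*only* medication persistence separates the classes: both classes get the
same expected number of full-span Adcirca mentions (strength matched,
durability ≈ 1 for everyone), but positives have multi-year records and
negatives months-long ones. It underpins the importance-recovery check
(a persistence feature should top the permutation ranking).

### What the generator does and does not emulate

It reproduces the *screening funnel* of a real record — a rare disease, an
order of magnitude more flagged non-cases than cases, confounders that
partially mimic each screened category — and hemodynamics consistent with
the target phenotype. It does not model visit structure, free text,
ICD-9↔10 transitions, coding drift, inter-rater disagreement, or partial
medication histories. Consequently, passing the end-to-end recovery checks
shows the pipeline is *correct and well-wired*, not that its test
characteristics would transfer to a real EMR: the planted signal is far
cleaner than reality, which is why desk-scale AUCs saturate near 1.0
while real-world analogues report ~0.96.

Two structural consequences of the clean signal are worth noting. Because
every true-PAH record flags all three screening categories, ranked review
consumes every planted case at the default budget, so the refinement stage
confirms ~0 *new* cases and in-population deployment can rediscover only
final-test-set cases. The deployment-recovery check therefore scores a
fresh cohort drawn from the same generative process, which measures the
same property with adequate n.

## Problem sizes and numerical choices

Desk-scale studies (tests, the acceptance script, the shipped demo config)
use 20,000–25,000-patient populations, review budget 980, 3-fold
single-repeat cross-validation and 3 + 2 Bayesian evaluations over reduced
bounds (RF 100–300 trees, XGBoost 30–150 rounds) — ample for the strongly
separable planted signal; `TrainingConfig()` defaults retain the
full-scale settings. Undefined confusion ratios (zero denominator) are
NaN, never 0. AUC is the rank-based Mann–Whitney statistic with tied
scores contributing ½. Resample CIs use the population-SD normal
approximation `mean ± 1.96·sd/√k`, clipped to [0, 1] (percentile
alternative available). Ranking and feature-matrix row order sort by
patient id; importance ties break by feature name. All randomness flows
from explicit `numpy` generators; equal seeds give byte-identical cohort
tables.

## Known limitations

* The adjudication oracle is purely hemodynamic; confirmatory imaging and
  pulmonary function testing are out of scope.
* Refinement-stage verification bias (only predicted positives reviewed)
  is reproduced by design, not corrected.
* The elastic net uses saga with a capped iteration budget; on perfectly
  separable data it can stop before full convergence, which is immaterial
  for ranking-based metrics but means coefficients are not publication-
  grade solutions of the penalized likelihood.
* PPV/NPV depend on the 0.5 threshold and on the synthetic prevalence;
  they are not transferable to populations with other case mixes.
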