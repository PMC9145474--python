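# pahphen

Computable phenotyping of **pulmonary arterial hypertension (PAH)** from
coded medical-record data — a tested, reusable implementation of a staged
machine-learning case-identification pipeline, together with a synthetic
longitudinal EMR generator so the whole procedure runs at desk scale
without access to any real patient record.

PAH is a rare (≈1/1,000,000 incidence) pre-capillary pulmonary
vasculopathy whose diagnosis requires right heart catheterization (RHC):
mPAP ≥ 25 mmHg, PVR ≥ 3 Wood units, PCWP ≤ 15 mmHg (the WSPH rule).
Finding PAH patients in claims data is hard because diagnosis codes are
imprecise and PAH drugs see off-label use. The approach implemented here:

1. **Screen** the population for any of three coded categories — a PH
   ICD-9/10 code, an RHC CPT code (93501 family), or a PAH-specific
   medication mention (brand or generic) — and rank flagged records by how
   many categories they carry.
2. **Adjudicate** top-ranked records against the WSPH hemodynamic rule
   (a simulated chart-review oracle), up to a review budget.
3. **Featurize** every screened variable `v` per patient as a
   *(strength, persistence, durability)* triple:
   `s_v` = mention count, `p_v` = days from first to last mention,
   `d_v = p_v / (record_end − first_mention) ∈ [0, 1]`.
4. **Train** random forest, XGBoost and elastic-net classifiers with
   Bayesian (GP + expected-improvement) hyperparameter optimization over
   repeated stratified cross-validated AUC, through development →
   refinement → final stages with strict train/test separation.
5. **Deploy** the final model on unreviewed patients and summarize the
   predicted cases (demographics, comorbidities, medication classes, RHC
   hemodynamics) — the claims-database use case.

See `docs/methods.md` for the model, the generator's strata, parameter
defaults and known limitations.

## Worked example

```python
from pahphen import AdjudicationRule, SimulationConfig, default_lexicon, simulate_cohort
from pahphen.models import desk_scale_config
from pahphen.pipeline import run_full_pipeline

population = simulate_cohort(SimulationConfig(n_patients=20_000, seed=1))
result = run_full_pipeline(
    population, default_lexicon(), AdjudicationRule(),
    review_budget=980, config=desk_scale_config(seed=1),
)

dev, fin = result.development, result.final
print(f"development cohort: {dev.n_cases} PAH / {dev.n_noncases} not-PAH "
      f"(initial {dev.model.algorithm}, test AUC {dev.characteristics.auc:.3f})")
print(f"refinement: {len(result.refinement_labels)} predicted positives reviewed")
print(f"final cohort: {fin.n_cases} PAH / {fin.n_noncases} not-PAH "
      f"-> train {len(fin.split.train_ids)}, test {len(fin.split.test_ids)}")
c = fin.characteristics
print(f"final test set: AUC {c.auc:.3f}, Se {c.sensitivity:.3f}, Sp {c.specificity:.3f}, "
      f"PPV {c.ppv:.3f}, NPV {c.npv:.3f}")
print(f"deployment: {len(result.predicted_case_ids)} predicted cases")
```

which prints:

```
development cohort: 185 PAH / 795 not-PAH (initial random_forest, test AUC 1.000)
refinement: 1188 predicted positives reviewed
final cohort: 184 PAH / 1932 not-PAH -> train 1694, test 422
final test set: AUC 1.000, Se 1.000, Sp 1.000, PPV 1.000, NPV 1.000
deployment: 36 predicted cases
```

Reading the numbers: the ranked screen concentrates the rare disease so
the 980-chart review budget yields a 185/795 development cohort; the
refinement stage reviews every record the initial model flags (confirmed
*and* refuted predictions enter the final cohort); the final model is
retrained from scratch on the pooled cohort and evaluated once on its
untouched 20% test set. The planted synthetic signal is deliberately
clean, so desk-scale test characteristics saturate near 1.0 — the checks
are about correctness of the machinery, not about real-world performance.

The same run is available from a shell:

```bash
pahphen run-all --seed 1 --out runs/demo
```

which writes the cohort tables, per-stage report JSONs, serialized models
and the deployment characteristics table under `runs/demo/`.

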