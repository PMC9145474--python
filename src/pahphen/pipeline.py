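"""Staged case-finding procedure: development -> refinement -> final -> deployment.

The pipeline mirrors a modified active-learning workflow for rare-disease
case identification in a coded EMR:

1. **Development stage** — screen the population, rank flagged records by
   the number of screened categories, adjudicate the top records up to a
   review budget, split 70/30, train all three classifier families, and
   keep the best by test AUC (the *Initial Algorithm*).
2. **Refinement stage** — deploy the initial algorithm on the remaining
   flagged records and adjudicate only the predicted positives (verified
   and refuted predictions both become labeled data; predicted negatives
   are never reviewed, an acknowledged source of verification bias).
3. **Final stage** — pool both labeled sets (dropping under-18 development
   patients), split 80/20 per class with floor rounding on the test side,
   and train all three families *from scratch*: the final model shares no
   fitted state with the initial one.
4. **Internal validation** — deploy the final model on every patient not
   consumed by earlier stages and aggregate demographics, comorbidities,
   medication classes and hemodynamics of the predicted cases.  No
   adjudication occurs at this stage, emulating use on a pure claims
   database.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from pahphen.adjudication import PAH, AdjudicationRule, adjudicate, review_batch
from pahphen.evaluation import (
    TestCharacteristics,
    auc_score,
    characteristics_table,
    confusion_metrics,
)
from pahphen.features import build_feature_matrix
from pahphen.lexicon import Lexicon
from pahphen.models import ALGORITHMS, FittedModel, TrainingConfig, predict, train_model
from pahphen.records import PatientRecord
from pahphen.screening import rank_screened, screen_population

#: Tie-break preference when test AUCs are equal.
ALGORITHM_PREFERENCE = ("random_forest", "xgboost", "elastic_net")


class StageError(RuntimeError):
    """A pipeline stage cannot proceed (empty cohort, missing class, overlap...)."""


@dataclass(frozen=True)
class CohortSplit:
    """A stratified train/test partition of labeled patient ids."""

    stage: str
    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    train_fraction: float
    stratified: bool
    seed: int

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise StageError("train and test ids overlap")


def stratified_split(
    labels: Mapping[str, str],
    test_fraction: float,
    seed: int,
    stage: str = "development",
    stratified: bool = True,
) -> CohortSplit:
    """Partition labeled ids with per-class floor rounding on the test side.

    Within each label class the test set takes ``floor(test_fraction * n)``
    shuffled members; the remainder trains.  With 653 cases / 1041
    non-cases at 20% this yields 130 + 208 = 338 test and 1356 train.
    """
    if not (0 < test_fraction < 1):
        raise ValueError("test_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    groups: dict[str, list[str]]
    if stratified:
        groups = {}
        for pid, lab in labels.items():
            groups.setdefault(lab, []).append(pid)
    else:
        groups = {"all": list(labels)}
    train: list[str] = []
    test: list[str] = []
    for lab in sorted(groups):
        ids = sorted(groups[lab])
        rng.shuffle(ids)
        n_test = int(np.floor(test_fraction * len(ids)))
        test.extend(ids[:n_test])
        train.extend(ids[n_test:])
    return CohortSplit(
        stage=stage,
        train_ids=tuple(sorted(train)),
        test_ids=tuple(sorted(test)),
        train_fraction=1 - test_fraction,
        stratified=stratified,
        seed=seed,
    )


@dataclass
class StageReport:
    """Everything a stage produced: cohort, model, test characteristics."""

    stage: str
    n_cases: int
    n_noncases: int
    model: Optional[FittedModel]
    characteristics: Optional[TestCharacteristics]
    consumed_ids: tuple[str, ...]
    labels: dict[str, str] = field(default_factory=dict)
    split: Optional[CohortSplit] = None
    per_algorithm: dict[str, dict] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "stage": self.stage,
            "n_cases": self.n_cases,
            "n_noncases": self.n_noncases,
            "algorithm": self.model.algorithm if self.model else None,
            "characteristics": self.characteristics.to_dict() if self.characteristics else None,
            "n_consumed": len(self.consumed_ids),
            "n_train": len(self.split.train_ids) if self.split else None,
            "n_test": len(self.split.test_ids) if self.split else None,
            "per_algorithm": self.per_algorithm,
        }


def _train_and_select(
    features: pd.DataFrame,
    labels: Mapping[str, str],
    split: CohortSplit,
    config: TrainingConfig,
    designate: Optional[str] = None,
) -> tuple[FittedModel, TestCharacteristics, dict[str, dict]]:
    """Train all three families on the split's training rows; evaluate once
    on the untouched test rows; return the selected model.

    ``designate`` pins the returned family regardless of test AUC (the
    reported per-algorithm AUCs still cover all three); otherwise the best
    test AUC wins, ties broken by ALGORITHM_PREFERENCE order.
    """
    y = pd.Series({pid: 1 if labels[pid] == PAH else 0 for pid in labels})
    X_train = features.loc[list(split.train_ids)]
    X_test = features.loc[list(split.test_ids)]
    y_train = y.loc[list(split.train_ids)]
    y_test = y.loc[list(split.test_ids)]
    assert not set(split.test_ids) & set(split.train_ids)  # leakage guard

    fitted: dict[str, FittedModel] = {}
    diag: dict[str, dict] = {}
    for i, algo in enumerate(ALGORITHMS):
        cfg = replace(config, algorithm=algo, seed=config.seed + 101 * (i + 1))
        model = train_model(X_train, y_train.to_numpy(), cfg)
        scores, pred = predict(model, X_test)
        chars = confusion_metrics(pred, y_test.to_numpy().astype(bool))
        chars.auc = auc_score(scores, y_test.to_numpy())
        fitted[algo] = model
        diag[algo] = {
            "test_auc": chars.auc,
            "test": chars.to_dict(),
            "cv_mean_auc": model.cv_mean_auc,
            "params": model.params,
        }

    if designate is not None:
        best = designate
    else:
        best = max(
            ALGORITHM_PREFERENCE,
            key=lambda a: (diag[a]["test_auc"], -ALGORITHM_PREFERENCE.index(a)),
        )
    model = fitted[best]
    scores, pred = predict(model, X_test)
    chars = confusion_metrics(pred, y_test.to_numpy().astype(bool))
    chars.auc = auc_score(scores, y_test.to_numpy())
    return model, chars, diag


def run_development_stage(
    population: Sequence[PatientRecord],
    lexicon: Lexicon,
    rule: AdjudicationRule,
    review_budget: int,
    config: TrainingConfig,
    test_fraction: float = 0.3,
) -> StageReport:
    """Screen, rank, adjudicate up to the review budget, and train the
    Initial Algorithm on a 70/30 stratified split of the reviewed records."""
    if review_budget <= 0:
        raise ValueError("review_budget must be positive")
    by_id = {r.patient_id: r for r in population}
    results = screen_population(list(population), lexicon)
    ranked = rank_screened(results)
    if not ranked:
        raise StageError("development stage: no records flagged by the screen")
    labeled = dict(review_batch(ranked, by_id, rule, budget=review_budget))
    n_cases = sum(1 for v in labeled.values() if v == PAH)
    if n_cases == 0 or n_cases == len(labeled):
        raise StageError(
            "development stage: adjudication produced a single class; "
            "increase the review budget"
        )
    features = build_feature_matrix([by_id[p] for p in labeled], lexicon)
    split = stratified_split(labeled, test_fraction, seed=config.seed, stage="development")
    model, chars, diag = _train_and_select(features, labeled, split, config)
    return StageReport(
        stage="development",
        n_cases=n_cases,
        n_noncases=len(labeled) - n_cases,
        model=model,
        characteristics=chars,
        consumed_ids=tuple(sorted(labeled)),
        labels=labeled,
        split=split,
        per_algorithm=diag,
    )


def run_refinement_stage(
    initial_model: FittedModel,
    remaining_flagged: Sequence[PatientRecord],
    lexicon: Lexicon,
    rule: AdjudicationRule,
    development_ids: Sequence[str] = (),
    threshold: Optional[float] = None,
) -> dict[str, str]:
    """Score the remaining flagged records and adjudicate only the
    predicted positives.

    Returns labels for exactly the predicted-positive records (confirmed
    cases and refuted non-cases alike); predicted negatives stay
    unreviewed.
    """
    overlap = {r.patient_id for r in remaining_flagged} & set(development_ids)
    if overlap:
        raise StageError(
            f"refinement stage: {len(overlap)} records overlap the development cohort"
        )
    if not remaining_flagged:
        return {}
    features = build_feature_matrix(list(remaining_flagged), lexicon)
    _, pred = predict(initial_model, features, threshold)
    by_id = {r.patient_id: r for r in remaining_flagged}
    positives = [pid for pid, p in zip(features.index, pred) if p]
    return {pid: adjudicate(by_id[pid], rule) for pid in positives}


def build_final_cohort(
    development_labels: Mapping[str, str],
    refinement_labels: Mapping[str, str],
    records: Mapping[str, PatientRecord],
    rule: AdjudicationRule = AdjudicationRule(),
) -> dict[str, str]:
    """Pool the two labeled sets, dropping under-18 development patients."""
    final: dict[str, str] = {}
    for pid, lab in development_labels.items():
        if records[pid].age_years < rule.adult_age_min:
            continue
        final[pid] = lab
    for pid, lab in refinement_labels.items():
        if pid in final and final[pid] != lab:
            raise StageError(f"conflicting labels for patient {pid}: {final[pid]} vs {lab}")
        final[pid] = lab
    return final


def run_final_stage(
    final_labels: Mapping[str, str],
    records: Mapping[str, PatientRecord],
    lexicon: Lexicon,
    config: TrainingConfig,
    test_fraction: float = 0.2,
    designate: Optional[str] = "random_forest",
) -> StageReport:
    """Retrain all three families from scratch on the pooled cohort (80/20).

    Every model parameter is freshly initialized — nothing is carried over
    from the initial algorithm.  The random forest is designated final by
    default (``designate=None`` selects the best test AUC instead).
    """
    labels = dict(final_labels)
    classes = set(labels.values())
    if len(classes) < 2:
        raise StageError("final stage: both classes must be present")
    features = build_feature_matrix([records[p] for p in labels], lexicon)
    split = stratified_split(labels, test_fraction, seed=config.seed + 17, stage="final")
    n_cases = sum(1 for v in labels.values() if v == PAH)
    for part in (split.train_ids, split.test_ids):
        if len({labels[p] for p in part}) < 2:
            raise StageError("final stage: a class is absent from one partition")
    model, chars, diag = _train_and_select(features, labels, split, config, designate=designate)
    return StageReport(
        stage="final",
        n_cases=n_cases,
        n_noncases=len(labels) - n_cases,
        model=model,
        characteristics=chars,
        consumed_ids=tuple(sorted(labels)),
        labels=labels,
        split=split,
        per_algorithm=diag,
    )


def internal_validation(
    final_model: FittedModel,
    full_population: Sequence[PatientRecord],
    consumed_ids: Sequence[str],
    lexicon: Lexicon,
    threshold: Optional[float] = None,
) -> tuple[list[str], dict]:
    """Deploy the final model on every non-consumed patient.

    All remaining patients are featurized (unflagged records contribute
    all-zero rows), scored, and the predicted positives aggregated into a
    deployment summary (demographics, comorbidities, medication classes,
    hemodynamic means over those with RHC data).  No adjudication occurs.
    Returns (predicted case ids, summary dict).
    """
    consumed = set(consumed_ids)
    unknown = consumed - {r.patient_id for r in full_population}
    if unknown:
        raise StageError(f"consumed ids not in population: {sorted(unknown)[:5]}...")
    remaining = [r for r in full_population if r.patient_id not in consumed]
    if not remaining:
        return [], characteristics_table([], lexicon)
    features = build_feature_matrix(remaining, lexicon)
    _, pred = predict(final_model, features, threshold)
    by_id = {r.patient_id: r for r in remaining}
    case_ids = [pid for pid, p in zip(features.index, pred) if p]
    summary = characteristics_table([by_id[p] for p in case_ids], lexicon)
    return case_ids, summary


@dataclass
class PipelineResult:
    development: StageReport
    refinement_labels: dict[str, str]
    final: StageReport
    predicted_case_ids: list[str]
    validation_summary: dict

    def to_dict(self) -> dict:
        return {
            "development": self.development.to_dict(),
            "n_refinement_reviewed": len(self.refinement_labels),
            "n_refinement_confirmed": sum(
                1 for v in self.refinement_labels.values() if v == PAH
            ),
            "final": self.final.to_dict(),
            "n_predicted_cases_validation": len(self.predicted_case_ids),
            "validation_summary": self.validation_summary,
        }


def run_full_pipeline(
    population: Sequence[PatientRecord],
    lexicon: Lexicon,
    rule: AdjudicationRule,
    review_budget: int,
    config: TrainingConfig,
    threshold: Optional[float] = None,
) -> PipelineResult:
    """Development -> refinement -> final -> internal validation, end to end."""
    dev = run_development_stage(population, lexicon, rule, review_budget, config)
    results = screen_population(list(population), lexicon)
    flagged_ids = {r.patient_id for r in results if r.flagged}
    by_id = {r.patient_id: r for r in population}
    remaining = [by_id[p] for p in sorted(flagged_ids - set(dev.consumed_ids))]
    ref_labels = run_refinement_stage(
        dev.model, remaining, lexicon, rule, dev.consumed_ids, threshold
    )
    final_labels = build_final_cohort(dev.labels, ref_labels, by_id, rule)
    final = run_final_stage(final_labels, by_id, lexicon, replace(config, seed=config.seed + 7919))
    # Deployment excludes every record the final model was trained or tuned
    # on; the final test set was only ever scored, so it remains deployable.
    consumed = sorted(
        (set(dev.consumed_ids) | set(ref_labels)) - set(final.split.test_ids)
    )
    case_ids, summary = internal_validation(final.model, population, consumed, lexicon, threshold)
    return PipelineResult(
        development=dev,
        refinement_labels=ref_labels,
        final=final,
        predicted_case_ids=case_ids,
        validation_summary=summary,
    )
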