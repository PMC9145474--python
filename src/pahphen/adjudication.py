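"""Hemodynamic chart-review oracle.

Stands in for expert manual chart review: a record is adjudicated PAH when
it carries right-heart-catheterization hemodynamics satisfying the WSPH
pre-capillary rule — mPAP >= 25 mmHg, PVR >= 3 Wood units and PCWP <= 15
mmHg, all thresholds inclusive.  A record without hemodynamics cannot be
confirmed and adjudicates not_PAH: the gold standard requires a right heart
catheterization, and a binary label is what trains the classifiers.
Adjudication is deterministic, idempotent and order-independent per record.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from pahphen.records import PatientRecord

PAH = "PAH"
NOT_PAH = "not_PAH"


@dataclass(frozen=True)
class AdjudicationRule:
    """WSPH hemodynamic thresholds plus the adult-age floor used downstream."""

    mpap_min: float = 25.0  # mmHg
    pvr_min: float = 3.0  # Wood units
    pcwp_max: float = 15.0  # mmHg
    adult_age_min: float = 18.0  # years

    def __post_init__(self) -> None:
        if min(self.mpap_min, self.pvr_min, self.pcwp_max, self.adult_age_min) <= 0:
            raise ValueError("all adjudication thresholds must be positive")


def adjudicate(record: PatientRecord, rule: AdjudicationRule = AdjudicationRule()) -> str:
    """Label one record PAH or not_PAH from its hemodynamics."""
    h = record.hemodynamics
    if h is None:
        return NOT_PAH
    if h.mPAP >= rule.mpap_min and h.PVR >= rule.pvr_min and h.PCWP <= rule.pcwp_max:
        return PAH
    return NOT_PAH


def review_batch(
    candidates: Iterable[str],
    records: Mapping[str, PatientRecord],
    rule: AdjudicationRule = AdjudicationRule(),
    budget: int = 0,
) -> list[tuple[str, str]]:
    """Adjudicate the first ``budget`` candidates in the given order.

    Returns (patient_id, label) pairs for exactly the reviewed prefix;
    candidates beyond the budget are untouched.
    """
    if budget < 0:
        raise ValueError("review budget must be non-negative")
    labeled: list[tuple[str, str]] = []
    for pid in candidates:
        if len(labeled) >= budget:
            break
        labeled.append((pid, adjudicate(records[pid], rule)))
    return labeled
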