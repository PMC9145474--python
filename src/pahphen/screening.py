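"""Three-category screening tool for possible PAH.

A record is flagged when it carries at least one event in any of the three
screened categories — a primary-pulmonary-hypertension ICD code, a right-
heart-catheterization CPT code, or a PAH-specific medication mention.
Flagged records are ranked by the number of distinct categories present
(0–3) so a limited chart-review budget is spent on the records most likely
to be true PAH.  Screening is strictly label-blind: it reads only the
events and the lexicon.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from pahphen.lexicon import Lexicon
from pahphen.records import PatientRecord

CATEGORIES = ("icd", "cpt", "med")


@dataclass(frozen=True)
class ScreenResult:
    patient_id: str
    icd: bool
    cpt: bool
    med: bool

    @property
    def n_features(self) -> int:
        return int(self.icd) + int(self.cpt) + int(self.med)

    @property
    def flagged(self) -> bool:
        return self.n_features >= 1


def screen_record(record: PatientRecord, lexicon: Lexicon) -> ScreenResult:
    """Flag each screened category present in a patient's events."""
    flags = {c: False for c in CATEGORIES}
    for ev in record.events:
        hit = lexicon.match(ev.vocabulary, ev.code)
        if hit is not None:
            flags[hit[0]] = True
            if all(flags.values()):
                break
    return ScreenResult(record.patient_id, flags["icd"], flags["cpt"], flags["med"])


def screen_population(records: list[PatientRecord], lexicon: Lexicon) -> list[ScreenResult]:
    return [screen_record(r, lexicon) for r in records]


def rank_screened(results: list[ScreenResult]) -> list[str]:
    """Flagged patient ids, most screened categories first.

    Ties on the category count break by ascending patient id so the review
    order is deterministic.  Unflagged patients are excluded.
    """
    flagged = [r for r in results if r.flagged]
    flagged.sort(key=lambda r: (-r.n_features, r.patient_id))
    return [r.patient_id for r in flagged]


def screening_table(results: list[ScreenResult]) -> pd.DataFrame:
    """Screening output as a table (patient_id, flagged, icd, cpt, med, n_features)."""
    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in results],
            "flagged": [r.flagged for r in results],
            "icd": [r.icd for r in results],
            "cpt": [r.cpt for r in results],
            "med": [r.med for r in results],
            "n_features": [r.n_features for r in results],
        }
    )
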