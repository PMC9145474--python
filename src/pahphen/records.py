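"""Core patient-level data containers.

A patient's coded medical record is modelled as a demographic header, a
record span ``[record_start, record_end]``, a list of dated coded events
(diagnoses, procedures, medication mentions), and an optional right-heart-
catheterization (RHC) hemodynamic profile.  Synthetic records additionally
carry the generating stratum and a latent truth label which downstream
pipeline stages must never read (only the adjudication oracle and final
scoring of simulation experiments may).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Optional

VOCABULARIES = ("ICD9", "ICD10", "CPT", "MED")

#: Fixed body-surface-area (m^2) used to derive cardiac index from cardiac
#: output; a single adult constant since no anthropometric model is carried.
BSA_M2 = 1.9


class DataIntegrityError(ValueError):
    """An input table or record violates a structural invariant."""


@dataclass(frozen=True)
class EventRecord:
    """One dated coded mention for one patient (whole-day granularity)."""

    date: dt.date
    vocabulary: str  # one of VOCABULARIES
    code: str

    def __post_init__(self) -> None:
        if self.vocabulary not in VOCABULARIES:
            raise DataIntegrityError(
                f"unknown vocabulary {self.vocabulary!r}; expected one of {VOCABULARIES}"
            )
        if not self.code:
            raise DataIntegrityError("event code must be non-empty")


@dataclass(frozen=True)
class Hemodynamics:
    """Right-heart-catheterization measurements.

    mRA, mPAP, PCWP in mmHg; CO in L/min; CI in L/min/m^2; PVR in Wood
    units.  PVR is tied to the other measurements through the identity
    PVR = (mPAP - PCWP) / CO.
    """

    mRA: float
    mPAP: float
    PCWP: float
    CO: float
    CI: float
    PVR: float

    def __post_init__(self) -> None:
        if min(self.mRA, self.mPAP, self.PCWP) < 0:
            raise DataIntegrityError("pressures must be non-negative")
        if self.CO <= 0:
            raise DataIntegrityError("cardiac output must be positive")
        expected = (self.mPAP - self.PCWP) / self.CO
        scale = max(1.0, abs(expected))
        if abs(self.PVR - expected) > 1e-6 * scale:
            raise DataIntegrityError(
                f"PVR={self.PVR} inconsistent with (mPAP-PCWP)/CO={expected:.6f}"
            )

    @classmethod
    def from_pressures(cls, mRA: float, mPAP: float, PCWP: float, CO: float) -> "Hemodynamics":
        """Build a consistent profile, deriving PVR and CI (BSA fixed at 1.9 m^2)."""
        return cls(
            mRA=mRA,
            mPAP=mPAP,
            PCWP=PCWP,
            CO=CO,
            CI=CO / BSA_M2,
            PVR=(mPAP - PCWP) / CO,
        )


@dataclass
class PatientRecord:
    """Demographics, record span, coded events and optional hemodynamics."""

    patient_id: str
    age_years: float
    sex: str  # "female" | "male"
    record_start: dt.date
    record_end: dt.date
    events: list[EventRecord] = field(default_factory=list)
    hemodynamics: Optional[Hemodynamics] = None
    comorbidity_codes: list[str] = field(default_factory=list)
    # Synthetic-only provenance; never consumed by screening/features/models.
    truth_label: Optional[str] = None  # "PAH" | "not_PAH"
    stratum: Optional[str] = None

    def __post_init__(self) -> None:
        if self.record_start > self.record_end:
            raise DataIntegrityError(
                f"patient {self.patient_id}: record_start after record_end"
            )
        if self.age_years < 0:
            raise DataIntegrityError(f"patient {self.patient_id}: negative age")

    @property
    def span_days(self) -> int:
        """Record length in whole days."""
        return (self.record_end - self.record_start).days

    def validate_events(self) -> None:
        """Raise if any event falls outside the record span."""
        for ev in self.events:
            if not (self.record_start <= ev.date <= self.record_end):
                raise DataIntegrityError(
                    f"patient {self.patient_id}: event {ev.vocabulary}:{ev.code} on "
                    f"{ev.date.isoformat()} lies outside span "
                    f"[{self.record_start.isoformat()}, {self.record_end.isoformat()}]"
                )
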