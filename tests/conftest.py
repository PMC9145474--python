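import datetime as dt

import pytest

from pahphen.lexicon import default_lexicon
from pahphen.records import EventRecord, Hemodynamics, PatientRecord
from pahphen.synthetic import EPOCH, SimulationConfig, simulate_cohort


def make_record(
    patient_id="P1",
    span=200,
    events=(),
    age=50.0,
    sex="female",
    hemodynamics=None,
    comorbidities=(),
):
    """Build a patient record from (day, vocabulary, code) event tuples."""
    return PatientRecord(
        patient_id=patient_id,
        age_years=age,
        sex=sex,
        record_start=EPOCH,
        record_end=EPOCH + dt.timedelta(days=span),
        events=[
            EventRecord(EPOCH + dt.timedelta(days=d), voc, code) for d, voc, code in events
        ],
        hemodynamics=hemodynamics,
        comorbidity_codes=list(comorbidities),
    )


def hemo(mpap, pcwp, co=5.0, mra=8.0):
    return Hemodynamics.from_pressures(mra, mpap, pcwp, co)


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


@pytest.fixture(scope="session")
def small_cohort():
    """A 2,000-patient synthetic population shared across read-only tests."""
    return simulate_cohort(SimulationConfig(n_patients=2000, seed=11))
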