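"""Delimited-table readers/writers and run configuration.

Interchange format is deliberately plain: comma-separated UTF-8 tables
with a mandatory header row and ISO-8601 dates.

* ``events.csv`` — patient_id, date, vocabulary, code
* ``patients.csv`` — patient_id, age_years, sex, record_start, record_end,
  comorbidities (semicolon-joined)
* ``hemodynamics.csv`` — patient_id, mRA, mPAP, PCWP, CO, CI, PVR
* ``truth.csv`` — patient_id, truth_label, stratum (synthetic provenance;
  written to a separate file so pipeline stages cannot accidentally read
  it — only the simulation oracle and final scoring may).
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from pahphen.adjudication import AdjudicationRule
from pahphen.lexicon import Lexicon, default_lexicon
from pahphen.models import TrainingConfig, desk_scale_config
from pahphen.records import (
    VOCABULARIES,
    DataIntegrityError,
    EventRecord,
    Hemodynamics,
    PatientRecord,
)
from pahphen.synthetic import SimulationConfig

EVENTS_FILE = "events.csv"
PATIENTS_FILE = "patients.csv"
HEMODYNAMICS_FILE = "hemodynamics.csv"
TRUTH_FILE = "truth.csv"


# -- writing -----------------------------------------------------------------


def write_cohort(records: list[PatientRecord], outdir: Path | str) -> dict[str, Path]:
    """Write the four cohort tables; truth/stratum go to their own file."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ev_rows, pat_rows, hemo_rows, truth_rows = [], [], [], []
    for r in records:
        pat_rows.append(
            {
                "patient_id": r.patient_id,
                "age_years": r.age_years,
                "sex": r.sex,
                "record_start": r.record_start.isoformat(),
                "record_end": r.record_end.isoformat(),
                "comorbidities": ";".join(r.comorbidity_codes),
            }
        )
        for e in r.events:
            ev_rows.append(
                {
                    "patient_id": r.patient_id,
                    "date": e.date.isoformat(),
                    "vocabulary": e.vocabulary,
                    "code": e.code,
                }
            )
        if r.hemodynamics is not None:
            h = r.hemodynamics
            # full float repr so the PVR/CI identities survive the round-trip
            hemo_rows.append(
                {
                    "patient_id": r.patient_id,
                    "mRA": h.mRA,
                    "mPAP": h.mPAP,
                    "PCWP": h.PCWP,
                    "CO": h.CO,
                    "CI": h.CI,
                    "PVR": h.PVR,
                }
            )
        if r.truth_label is not None:
            truth_rows.append(
                {"patient_id": r.patient_id, "truth_label": r.truth_label, "stratum": r.stratum}
            )
    paths = {}
    for name, rows, cols in (
        (EVENTS_FILE, ev_rows, ["patient_id", "date", "vocabulary", "code"]),
        (PATIENTS_FILE, pat_rows,
         ["patient_id", "age_years", "sex", "record_start", "record_end", "comorbidities"]),
        (HEMODYNAMICS_FILE, hemo_rows, ["patient_id", "mRA", "mPAP", "PCWP", "CO", "CI", "PVR"]),
        (TRUTH_FILE, truth_rows, ["patient_id", "truth_label", "stratum"]),
    ):
        path = outdir / name
        pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
        paths[name] = path
    return paths


# -- reading -----------------------------------------------------------------


def _parse_date(value: str, row: int, table: str) -> dt.date:
    try:
        return dt.date.fromisoformat(str(value))
    except ValueError as exc:
        raise DataIntegrityError(f"{table} row {row}: unparseable date {value!r}") from exc


def load_tables(
    patients_path: Path | str,
    events_path: Path | str,
    hemodynamics_path: Optional[Path | str] = None,
) -> list[PatientRecord]:
    """Join events and hemodynamics onto patients; validate as we go.

    Unknown vocabularies, unparseable dates, orphan events (an id absent
    from the patients table) and events outside a patient's record span are
    all rejected with the offending row number.
    """
    pats = pd.read_csv(patients_path, dtype={"patient_id": str}, keep_default_na=False)
    events = pd.read_csv(events_path, dtype={"patient_id": str, "code": str},
                         keep_default_na=False)
    records: dict[str, PatientRecord] = {}
    for i, row in enumerate(pats.itertuples(index=False), start=2):  # 1-based + header
        start = _parse_date(row.record_start, i, "patients")
        end = _parse_date(row.record_end, i, "patients")
        comorbid = [c for c in str(getattr(row, "comorbidities", "")).split(";") if c]
        if row.patient_id in records:
            raise DataIntegrityError(f"patients row {i}: duplicate patient_id {row.patient_id}")
        records[row.patient_id] = PatientRecord(
            patient_id=row.patient_id,
            age_years=float(row.age_years),
            sex=str(row.sex),
            record_start=start,
            record_end=end,
            comorbidity_codes=comorbid,
        )
    for i, row in enumerate(events.itertuples(index=False), start=2):
        rec = records.get(row.patient_id)
        if rec is None:
            raise DataIntegrityError(
                f"events row {i}: orphan event for unknown patient {row.patient_id!r}"
            )
        if row.vocabulary not in VOCABULARIES:
            raise DataIntegrityError(
                f"events row {i}: unknown vocabulary {row.vocabulary!r}"
            )
        date = _parse_date(row.date, i, "events")
        if not (rec.record_start <= date <= rec.record_end):
            raise DataIntegrityError(
                f"events row {i}: event on {date.isoformat()} outside span of {row.patient_id}"
            )
        rec.events.append(EventRecord(date, row.vocabulary, row.code))
    if hemodynamics_path is not None and Path(hemodynamics_path).exists():
        hemo = pd.read_csv(hemodynamics_path, dtype={"patient_id": str})
        for i, row in enumerate(hemo.itertuples(index=False), start=2):
            rec = records.get(row.patient_id)
            if rec is None:
                raise DataIntegrityError(
                    f"hemodynamics row {i}: unknown patient {row.patient_id!r}"
                )
            rec.hemodynamics = Hemodynamics(
                mRA=float(row.mRA), mPAP=float(row.mPAP), PCWP=float(row.PCWP),
                CO=float(row.CO), CI=float(row.CI), PVR=float(row.PVR),
            )
    for rec in records.values():
        rec.events.sort(key=lambda e: (e.date, e.vocabulary, e.code))
    return [records[k] for k in sorted(records)]


def load_truth(path: Path | str) -> pd.DataFrame:
    """The synthetic oracle table, loaded separately from patient records."""
    return pd.read_csv(path, dtype={"patient_id": str}).set_index("patient_id")


# -- lexicon & config --------------------------------------------------------


def load_lexicon(path: Optional[Path | str]) -> Lexicon:
    if path is None:
        return default_lexicon()
    with open(path) as fh:
        return Lexicon.from_dict(yaml.safe_load(fh))


def save_lexicon(lexicon: Lexicon, path: Path | str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(lexicon.to_dict(), fh, sort_keys=False)


@dataclasses.dataclass
class RunConfig:
    """Master configuration: one seed deterministically drives every stage."""

    simulation: SimulationConfig
    training: TrainingConfig
    rule: AdjudicationRule
    review_budget: int = 980
    threshold: float = 0.5
    seed: int = 0
    lexicon_path: Optional[str] = None

    @classmethod
    def from_dict(cls, d: dict, seed: Optional[int] = None) -> "RunConfig":
        master = int(d.get("seed", 0) if seed is None else seed)
        sim_d = dict(d.get("simulation", {}))
        sim_d["seed"] = master
        sim_kwargs = {}
        for f in dataclasses.fields(SimulationConfig):
            if f.name in sim_d:
                v = sim_d[f.name]
                sim_kwargs[f.name] = tuple(v) if f.name == "record_span_days" else v
        train_d = dict(d.get("training", {}))
        train_d["seed"] = master + 1000
        scale = train_d.pop("scale", "desk")
        base = desk_scale_config(seed=master + 1000) if scale == "desk" else TrainingConfig()
        training = dataclasses.replace(base, **{
            k: v for k, v in train_d.items()
            if k in {f.name for f in dataclasses.fields(TrainingConfig)}
        })
        rule = AdjudicationRule(**d.get("adjudication", {}))
        return cls(
            simulation=SimulationConfig(**sim_kwargs),
            training=training,
            rule=rule,
            review_budget=int(d.get("review_budget", 980)),
            threshold=float(d.get("threshold", 0.5)),
            seed=master,
            lexicon_path=d.get("lexicon"),
        )

    @classmethod
    def load(cls, path: Optional[Path | str], seed: Optional[int] = None) -> "RunConfig":
        if path is None:
            return cls.from_dict({}, seed=seed)
        p = Path(path)
        if not p.exists():
            raise FileNotFoundError(f"config file not found: {p}")
        with open(p) as fh:
            d = yaml.safe_load(fh) or {}
        if d.get("lexicon") and not Path(d["lexicon"]).exists():
            raise FileNotFoundError(f"lexicon file not found: {d['lexicon']}")
        return cls.from_dict(d, seed=seed)

    def lexicon(self) -> Lexicon:
        return load_lexicon(self.lexicon_path)


def write_json(obj: dict, path: Path | str) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    import numpy as np

    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
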