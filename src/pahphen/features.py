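"""Strength / persistence / durability feature calculus.

Every screened variable (each lexicon ICD code, CPT code, and medication
name) is summarized per patient by three longitudinal scalars:

* **strength** — the number of mentions of that variable anywhere in the
  record (same-day duplicates each count);
* **persistence** — the number of whole days the variable stayed on the
  record, i.e. days from its first to its last mention (a single mention
  persists 0 days);
* **durability** — persistence divided by the length of the record after
  the first mention, ``persistence / (record_end - first_mention)``, with
  0/0 defined as 0.  Durability lives in [0, 1]: near 1 means the variable
  was present essentially from first appearance to the end of the record
  (sustained therapy), near 0 means an isolated or late one-off mention.

The production path (:func:`build_feature_matrix`) is vectorized over a
long event frame; the per-record :func:`extract_features` is the simple
scalar form of the same definitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from pahphen.lexicon import Lexicon
from pahphen.records import DataIntegrityError, PatientRecord

COMPONENTS = ("strength", "persistence", "durability")


def feature_columns(lexicon: Lexicon) -> list[str]:
    """The fixed feature-matrix column order: ``{variable}__{component}``."""
    return [f"{v}__{c}" for v in lexicon.variables() for c in COMPONENTS]


@dataclass(frozen=True)
class FeatureVector:
    """Per-patient strength/persistence/durability triples, keyed by variable."""

    patient_id: str
    values: dict[str, tuple[int, int, float]]  # variable -> (strength, persistence, durability)

    def strength(self, variable: str) -> int:
        return self.values[variable][0]

    def persistence(self, variable: str) -> int:
        return self.values[variable][1]

    def durability(self, variable: str) -> float:
        return self.values[variable][2]

    def as_row(self, lexicon: Lexicon) -> dict[str, float]:
        row: dict[str, float] = {}
        for v in lexicon.variables():
            s, p, d = self.values[v]
            row[f"{v}__strength"] = s
            row[f"{v}__persistence"] = p
            row[f"{v}__durability"] = d
        return row


def extract_features(record: PatientRecord, lexicon: Lexicon) -> FeatureVector:
    """Compute the strength/persistence/durability triple for every variable."""
    record.validate_events()
    firsts: dict[str, int] = {}
    lasts: dict[str, int] = {}
    counts: dict[str, int] = {}
    start = record.record_start
    for ev in record.events:
        hit = lexicon.match(ev.vocabulary, ev.code)
        if hit is None:
            continue
        var = hit[1]
        day = (ev.date - start).days
        counts[var] = counts.get(var, 0) + 1
        if var not in firsts or day < firsts[var]:
            firsts[var] = day
        if var not in lasts or day > lasts[var]:
            lasts[var] = day
    span = record.span_days
    values: dict[str, tuple[int, int, float]] = {}
    for v in lexicon.variables():
        n = counts.get(v, 0)
        if n == 0:
            values[v] = (0, 0, 0.0)
            continue
        persistence = lasts[v] - firsts[v]
        tail = span - firsts[v]  # days of record after first appearance
        durability = persistence / tail if tail > 0 else 0.0
        values[v] = (n, persistence, durability)
    return FeatureVector(record.patient_id, values)


def build_feature_matrix(records: list[PatientRecord], lexicon: Lexicon) -> pd.DataFrame:
    """One row per patient (sorted by id), 3 x |variables| columns.

    Vectorized over a long (patient, variable, day) frame; identical to
    applying :func:`extract_features` record by record.
    """
    cols = feature_columns(lexicon)
    ids = [r.patient_id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise DataIntegrityError(f"duplicate patient ids: {dupes}")
    if not records:
        return pd.DataFrame(columns=cols, index=pd.Index([], name="patient_id"))

    rows = []
    for r in records:
        r.validate_events()
        start = r.record_start
        for ev in r.events:
            hit = lexicon.match(ev.vocabulary, ev.code)
            if hit is not None:
                rows.append((r.patient_id, hit[1], (ev.date - start).days))
    span = pd.Series({r.patient_id: r.span_days for r in records}, name="span")

    out = pd.DataFrame(
        0.0, index=pd.Index(sorted(ids), name="patient_id"), columns=cols
    )
    if rows:
        long = pd.DataFrame(rows, columns=["patient_id", "variable", "day"])
        agg = long.groupby(["patient_id", "variable"])["day"].agg(["count", "min", "max"])
        agg["persistence"] = agg["max"] - agg["min"]
        tail = span.reindex(agg.index.get_level_values(0)).to_numpy() - agg["min"].to_numpy()
        agg["durability"] = np.where(tail > 0, agg["persistence"] / np.where(tail > 0, tail, 1), 0.0)
        for comp, src in (("strength", "count"), ("persistence", "persistence"), ("durability", "durability")):
            wide = agg[src].unstack("variable")
            for var in wide.columns:
                out.loc[wide.index, f"{var}__{comp}"] = wide[var].fillna(0).to_numpy()
    return out
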