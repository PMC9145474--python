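"""Strength/persistence/durability calculus: frozen examples, reference
oracle equivalence, and growth monotonicity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pahphen.features import build_feature_matrix, extract_features, feature_columns
from pahphen.lexicon import default_lexicon
from pahphen.records import DataIntegrityError
from pahphen.synthetic import SimulationConfig, simulate_cohort

from .conftest import make_record


def naive_features(record, lexicon):
    """Independent reference: scan all events per variable, min/max days."""
    out = {}
    for v in lexicon.variables():
        days = []
        for ev in record.events:
            hit = lexicon.match(ev.vocabulary, ev.code)
            if hit is not None and hit[1] == v:
                days.append((ev.date - record.record_start).days)
        if not days:
            out[v] = (0, 0, 0.0)
            continue
        persistence = max(days) - min(days)
        tail = record.span_days - min(days)
        out[v] = (len(days), persistence, persistence / tail if tail > 0 else 0.0)
    return out


class TestExtractFeatures:
    def test_absent_variable_is_all_zero(self, lexicon):
        fv = extract_features(make_record(), lexicon)
        assert fv.values["Adcirca"] == (0, 0, 0.0)

    def test_hand_computed_example(self, lexicon):
        # Adcirca on days 10, 50, 100 of a 0-200 day record:
        # strength 3, persistence 100-10=90, durability 90/(200-10)=90/190
        rec = make_record(span=200, events=[(10, "MED", "Adcirca"), (50, "MED", "Adcirca"), (100, "MED", "Adcirca")])
        fv = extract_features(rec, lexicon)
        assert fv.strength("Adcirca") == 3
        assert fv.persistence("Adcirca") == 90
        assert fv.durability("Adcirca") == pytest.approx(90 / 190)

    def test_single_mention_on_final_day_has_zero_durability(self, lexicon):
        rec = make_record(span=200, events=[(200, "MED", "Adcirca")])
        fv = extract_features(rec, lexicon)
        assert (fv.strength("Adcirca"), fv.persistence("Adcirca"), fv.durability("Adcirca")) == (1, 0, 0.0)

    def test_same_day_duplicates_each_count(self, lexicon):
        rec = make_record(events=[(10, "MED", "Adcirca"), (10, "MED", "Adcirca")])
        assert extract_features(rec, lexicon).strength("Adcirca") == 2

    def test_event_outside_span_rejected_by_name(self, lexicon):
        rec = make_record(span=100)
        rec.events = make_record(span=300, events=[(250, "MED", "Adcirca")]).events
        with pytest.raises(DataIntegrityError, match="Adcirca"):
            extract_features(rec, lexicon)

    @given(
        days=st.lists(st.integers(0, 300), min_size=1, max_size=8),
        extra=st.integers(0, 300),
    )
    @settings(max_examples=60, deadline=None)
    def test_appending_mention_is_monotone(self, days, extra):
        """With record_end fixed, another mention never decreases any component."""
        lexicon = default_lexicon()
        base = make_record(span=300, events=[(d, "MED", "Adcirca") for d in days])
        grown = make_record(span=300, events=[(d, "MED", "Adcirca") for d in days + [extra]])
        f0 = extract_features(base, lexicon).values["Adcirca"]
        f1 = extract_features(grown, lexicon).values["Adcirca"]
        assert all(a >= b for a, b in zip(f1, f0))


class TestBuildFeatureMatrix:
    def test_empty_input_keeps_full_header(self, lexicon):
        fm = build_feature_matrix([], lexicon)
        assert list(fm.columns) == feature_columns(lexicon)
        assert len(fm) == 0

    def test_three_columns_per_variable(self, lexicon):
        fm = build_feature_matrix([make_record()], lexicon)
        assert fm.shape == (1, 3 * len(lexicon.variables()))

    def test_duplicate_patient_ids_rejected(self, lexicon):
        with pytest.raises(DataIntegrityError, match="duplicate"):
            build_feature_matrix([make_record(patient_id="X"), make_record(patient_id="X")], lexicon)

    def test_row_order_invariant_under_input_permutation(self, lexicon, small_cohort):
        subset = small_cohort[:50]
        fm1 = build_feature_matrix(subset, lexicon)
        fm2 = build_feature_matrix(list(reversed(subset)), lexicon)
        assert fm1.equals(fm2)

    def test_matches_naive_reference_on_random_records(self, lexicon):
        records = simulate_cohort(SimulationConfig(n_patients=300, seed=23))
        fm = build_feature_matrix(records, lexicon)
        for rec in records[::7]:
            ref = naive_features(rec, lexicon)
            for v, (s, p, d) in ref.items():
                assert fm.loc[rec.patient_id, f"{v}__strength"] == s
                assert fm.loc[rec.patient_id, f"{v}__persistence"] == p
                assert np.isclose(fm.loc[rec.patient_id, f"{v}__durability"], d)
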