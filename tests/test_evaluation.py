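"""Test-characteristic arithmetic, AUC oracle equivalence, CIs, summaries."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pahphen.evaluation import (
    auc_score,
    characteristics_frame,
    characteristics_table,
    confusion_metrics,
    resample_ci,
)

from .conftest import hemo, make_record


def pair_counting_auc(scores, labels):
    """O(n^2) concordant-pair oracle: ties count one half."""
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestConfusionMetrics:
    def test_hand_example(self):
        pred = [1] * 50 + [0] * 5 + [0] * 100 + [1] * 10
        true = [1] * 50 + [1] * 5 + [0] * 100 + [0] * 10
        m = confusion_metrics(pred, true)
        assert (m.tp, m.fn, m.tn, m.fp) == (50, 5, 100, 10)
        assert m.sensitivity == pytest.approx(0.9091, abs=1e-4)
        assert m.specificity == pytest.approx(0.9091, abs=1e-4)
        assert m.ppv == pytest.approx(0.8333, abs=1e-4)
        assert m.npv == pytest.approx(0.9524, abs=1e-4)

    def test_all_correct_gives_ones(self):
        m = confusion_metrics([1, 0, 1], [1, 0, 1])
        assert (m.sensitivity, m.specificity, m.ppv, m.npv) == (1.0, 1.0, 1.0, 1.0)

    def test_no_predicted_positives_makes_ppv_undefined_not_zero(self):
        m = confusion_metrics([0, 0, 0], [1, 0, 1])
        assert math.isnan(m.ppv)
        assert m.sensitivity == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            confusion_metrics([1, 0], [1])

    @given(
        pred=st.lists(st.booleans(), min_size=1, max_size=60),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=80, deadline=None)
    def test_metric_identities_on_random_tables(self, pred, seed):
        rng = np.random.default_rng(seed)
        true = rng.random(len(pred)) < 0.5
        m = confusion_metrics(pred, true)
        assert m.tp + m.fp + m.fn + m.tn == m.n == len(pred)
        for value, num, den in [
            (m.sensitivity, m.tp, m.tp + m.fn),
            (m.specificity, m.tn, m.tn + m.fp),
            (m.ppv, m.tp, m.tp + m.fp),
            (m.npv, m.tn, m.tn + m.fn),
        ]:
            if den == 0:
                assert math.isnan(value)
            else:
                assert abs(value - num / den) < 1e-12


class TestAucScore:
    def test_perfect_ranking(self):
        assert auc_score([0.9, 0.8, 0.4, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert auc_score([0.3] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            auc_score([0.1, 0.2], [1, 1])

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            scores = np.round(rng.random(50), 2)  # rounding forces ties
            labels = rng.random(50) < 0.4
            if labels.all() or not labels.any():
                continue
            assert auc_score(scores, labels) == pytest.approx(
                pair_counting_auc(scores, labels), abs=1e-12
            )

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        scores = rng.random(40)
        labels = rng.random(40) < 0.5
        assert auc_score(scores, labels) == pytest.approx(
            auc_score(np.exp(3 * scores), labels), abs=1e-12
        )


class TestResampleCI:
    def test_constant_samples_zero_width(self):
        mean, lo, hi = resample_ci([0.9, 0.9, 0.9])
        assert (mean, lo, hi) == (0.9, 0.9, 0.9)

    def test_two_sample_closed_form(self):
        mean, lo, hi = resample_ci([0.9, 1.0])
        assert mean == pytest.approx(0.95)
        # half-width 1.96 * 0.05 / sqrt(2) ~ 0.0693; upper bound clips at 1
        assert mean - lo == pytest.approx(1.959964 * 0.05 / math.sqrt(2), abs=1e-4)
        assert hi == 1.0

    def test_fewer_than_two_samples_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            resample_ci([0.9])

    def test_coverage_of_normal_draws(self):
        """~95% nominal coverage over 100 replicates of 30 draws."""
        rng = np.random.default_rng(42)
        covered = 0
        for _ in range(100):
            samples = rng.normal(0.94, 0.01, size=30)
            _, lo, hi = resample_ci(samples)
            covered += lo <= 0.94 <= hi
        assert covered >= 90


class TestCharacteristicsTable:
    def test_zero_cases(self):
        s = characteristics_table([])
        assert s["n"] == 0 and s["n_hemodynamics"] == 0
        assert math.isnan(s["age_mean"])

    def test_two_case_hand_arithmetic(self):
        cases = [
            make_record(patient_id="a", age=40.0, sex="female"),
            make_record(patient_id="b", age=60.0, sex="male"),
        ]
        s = characteristics_table(cases)
        assert s["age_mean"] == pytest.approx(50.0)
        assert s["age_sd"] == pytest.approx(14.1, abs=0.05)
        assert s["pct_female"] == pytest.approx(50.0)

    def test_summary_schema_and_rendering(self):
        cases = [
            make_record(
                patient_id="a",
                events=[(1, "MED", "Tracleer"), (2, "MED", "Revatio")],
                hemodynamics=hemo(49.8, 11.3, co=4.8),
                comorbidities=["CTD"],
            )
        ]
        s = characteristics_table(cases)
        assert set(s["medication_class_pct"]) == {"ERA", "GC_stimulator", "PDE5_inhibitor", "prostanoid"}
        assert s["medication_class_pct"]["ERA"] == 100.0
        assert s["medication_class_pct"]["prostanoid"] == 0.0
        assert s["n_hemodynamics"] == 1
        assert set(s["hemodynamics"]) == {"mRA", "mPAP", "PCWP", "CO", "CI", "PVR"}
        frame = characteristics_frame(s)
        assert {"characteristic", "value"} == set(frame.columns)
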