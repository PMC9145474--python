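"""Synthetic EMR generator: determinism, stratum signals, calibration."""

import numpy as np
import pytest

from pahphen import io as pio
from pahphen.adjudication import NOT_PAH, PAH, AdjudicationRule
from pahphen.screening import screen_record
from pahphen.synthetic import (
    ConfigurationError,
    SimulationConfig,
    plant_signal,
    sample_hemodynamics,
    simulate_cohort,
    simulate_persistence_contrast,
    truncated_hemodynamic_moments,
)

from .conftest import make_record


class TestConfigValidation:
    def test_weights_must_sum_to_one_with_prevalence(self):
        cfg = SimulationConfig(pah_prevalence=0.02)  # default weights sum to 0.99 + 0.02
        with pytest.raises(ConfigurationError, match="sum to 1"):
            cfg.validate()

    def test_negative_rate_named(self):
        cfg = SimulationConfig(
            mention_rate_per_year={**SimulationConfig().mention_rate_per_year,
                                   "true_pah": {"med": -1.0}}
        )
        with pytest.raises(ConfigurationError, match="mention_rate_per_year"):
            cfg.validate()

    def test_record_span_min_at_least_one_day(self):
        with pytest.raises(ConfigurationError, match="record_span"):
            SimulationConfig(record_span_days=(100.0, 10.0, 0)).validate()


class TestSimulateCohort:
    def test_zero_patients_gives_empty_list(self):
        assert simulate_cohort(SimulationConfig(n_patients=0, seed=1)) == []

    def test_zero_prevalence_forces_all_negative(self):
        cfg = SimulationConfig(
            n_patients=300,
            pah_prevalence=0.0,
            stratum_weights={"postcapillary_ph": 0.06, "offlabel_med_user": 0.03,
                             "code_only": 0.03, "background": 0.88},
            seed=2,
        )
        records = simulate_cohort(cfg)
        assert all(r.truth_label == NOT_PAH for r in records)

    def test_events_lie_within_record_span(self, small_cohort):
        for rec in small_cohort[::19]:
            rec.validate_events()

    def test_identical_seeds_give_byte_identical_tables(self, tmp_path):
        cfg = SimulationConfig(n_patients=10_000, seed=7)
        a = pio.write_cohort(simulate_cohort(cfg), tmp_path / "a")
        b = pio.write_cohort(simulate_cohort(cfg), tmp_path / "b")
        for name in a:
            assert a[name].read_bytes() == b[name].read_bytes()

    def test_realized_prevalence_is_binomial_scale(self, small_cohort):
        n_pah = sum(r.truth_label == PAH for r in small_cohort)
        # 3 sigma around 1% of 2000
        assert abs(n_pah - 20) <= 3 * np.sqrt(2000 * 0.01 * 0.99)


class TestPlantSignal:
    def _plant(self, stratum, seed=0, span=3650):
        cfg = SimulationConfig(seed=seed)
        rng = np.random.default_rng(seed)
        return plant_signal(make_record(span=span), stratum, cfg, rng)

    def test_unknown_stratum_rejected(self):
        with pytest.raises(ConfigurationError, match="stratum"):
            self._plant("mystery")

    def test_background_has_no_screened_category(self, lexicon):
        for seed in range(20):
            rec = self._plant("background", seed)
            assert screen_record(rec, lexicon).n_features == 0

    def test_true_pah_flags_all_three_categories(self, lexicon):
        for seed in range(100):
            rec = self._plant("true_pah", seed)
            assert screen_record(rec, lexicon).n_features == 3

    def test_offlabel_user_flags_med_but_not_icd(self, lexicon):
        for seed in range(20):
            res = screen_record(self._plant("offlabel_med_user", seed), lexicon)
            assert res.med and not res.icd

    def test_code_only_flags_icd_alone(self, lexicon):
        for seed in range(20):
            res = screen_record(self._plant("code_only", seed), lexicon)
            assert (res.icd, res.cpt, res.med) == (True, False, False)


class TestHemodynamics:
    def test_true_pah_draws_satisfy_wsph(self):
        rng = np.random.default_rng(0)
        p = SimulationConfig().hemodynamic_params["true_pah"]
        for _ in range(200):
            h = sample_hemodynamics("true_pah", p, rng)
            assert h.mPAP >= 25 and h.PCWP <= 15 and h.PVR >= 3

    def test_postcapillary_draws_have_elevated_wedge(self):
        rng = np.random.default_rng(0)
        p = SimulationConfig().hemodynamic_params["postcapillary_ph"]
        for _ in range(100):
            assert sample_hemodynamics("postcapillary_ph", p, rng).PCWP > 15

    def test_background_draws_fail_wsph(self):
        rng = np.random.default_rng(0)
        p = SimulationConfig().hemodynamic_params["background"]
        rule = AdjudicationRule()
        for _ in range(100):
            h = sample_hemodynamics("background", p, rng)
            assert not (h.mPAP >= rule.mpap_min and h.PVR >= rule.pvr_min and h.PCWP <= rule.pcwp_max)

    def test_sampler_calibrated_to_truncated_monte_carlo_mean(self):
        """Mean of 5,000 production draws ~ brute-force truncated mean."""
        cfg = SimulationConfig()
        rng = np.random.default_rng(77)
        draws = [sample_hemodynamics("true_pah", cfg.hemodynamic_params["true_pah"], rng)
                 for _ in range(5000)]
        mc = truncated_hemodynamic_moments(cfg, "true_pah", n=100_000, seed=5)
        for f in ("mPAP", "PCWP", "PVR"):
            sample_mean = np.mean([getattr(h, f) for h in draws])
            mc_mean, mc_sd = mc[f]
            assert abs(sample_mean - mc_mean) <= 3 * mc_sd / np.sqrt(5000)


def test_persistence_contrast_classes_differ_only_in_persistence(lexicon):
    from pahphen.features import build_feature_matrix

    records, labels = simulate_persistence_contrast(n=200, seed=3)
    fm = build_feature_matrix(records, lexicon)
    y = np.array([l == PAH for l in labels])[np.argsort([r.patient_id for r in records])]
    pers = fm["Adcirca__persistence"].to_numpy()
    strength = fm["Adcirca__strength"].to_numpy()
    dur = fm["Adcirca__durability"].to_numpy()
    assert pers[y].min() > pers[~y].max()  # persistence separates perfectly
    assert abs(strength[y].mean() - strength[~y].mean()) < 1.0  # strength ~ matched
    assert dur[y].mean() == pytest.approx(dur[~y].mean(), abs=0.05)  # durability ~ 1 for all
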