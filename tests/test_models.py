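"""Classifier training: separability, permutation null, prediction contracts,
optimization sanity and permutation importance."""

import numpy as np
import pandas as pd
import pytest

from pahphen.models import (
    ALGORITHMS,
    DESK_SCALE_SEARCH_SPACES,
    TrainingConfig,
    feature_importance,
    load_model,
    predict,
    save_model,
    train_model,
)


def tiny_config(algorithm, seed=0, **kw):
    defaults = dict(
        algorithm=algorithm,
        cv_folds=2,
        cv_repeats=1,
        opt_iterations=0,
        opt_initial=1,
        seed=seed,
        search_spaces=DESK_SCALE_SEARCH_SPACES,
    )
    defaults.update(kw)
    return TrainingConfig(**defaults)


def separable_frame(n=60, seed=0):
    rng = np.random.default_rng(seed)
    y = np.arange(n) % 2
    X = pd.DataFrame(
        {
            "drug__strength": np.where(y == 1, 10.0, 0.0),
            "drug__persistence": rng.normal(0, 0.1, n),
        }
    )
    return X, y


class TestTrainModel:
    @pytest.mark.parametrize("algorithm", ALGORITHMS)
    def test_separable_data_reaches_perfect_cv_auc(self, algorithm):
        X, y = separable_frame()
        model = train_model(X, y, tiny_config(algorithm))
        assert model.cv_mean_auc == 1.0
        assert len(model.cv_auc_samples) == 2  # folds x repeats

    def test_single_class_labels_rejected(self):
        X, y = separable_frame()
        with pytest.raises(ValueError, match="single class"):
            train_model(X, np.ones_like(y), tiny_config("xgboost"))

    def test_label_length_mismatch_rejected(self):
        X, y = separable_frame()
        with pytest.raises(ValueError, match="labels"):
            train_model(X, y[:-1], tiny_config("xgboost"))

    def test_shuffled_labels_give_null_auc(self):
        """Permutation null: mean CV AUC stays near one half."""
        rng = np.random.default_rng(99)
        aucs = []
        for seed in range(20):
            X = pd.DataFrame(rng.normal(size=(500, 8)),
                             columns=[f"f{i}" for i in range(8)])
            y = rng.permutation(np.arange(500) % 2)
            cfg = tiny_config("elastic_net", seed=seed, cv_folds=3)
            aucs.append(train_model(X, y, cfg).cv_mean_auc)
        assert abs(float(np.mean(aucs)) - 0.5) < 0.08

    def test_more_optimization_does_not_hurt(self):
        rng = np.random.default_rng(4)
        n = 200
        y = np.arange(n) % 2
        X = pd.DataFrame(
            {"sig": y + rng.normal(0, 1.5, n), "noise": rng.normal(size=n)}
        )
        short = train_model(X, y, tiny_config("elastic_net", opt_initial=1, opt_iterations=0))
        longer = train_model(X, y, tiny_config("elastic_net", opt_initial=4, opt_iterations=4))
        assert longer.cv_mean_auc >= short.cv_mean_auc - 0.02


class TestPredict:
    def setup_method(self):
        self.X, self.y = separable_frame()
        self.model = train_model(self.X, self.y, tiny_config("random_forest"))

    def test_all_zero_row_is_negative(self):
        row = pd.DataFrame({"drug__strength": [0.0], "drug__persistence": [0.0]})
        _, labels = predict(self.model, row)
        assert not labels[0]

    def test_threshold_zero_labels_everything_positive(self):
        _, labels = predict(self.model, self.X, threshold=0.0)
        assert labels.all()

    def test_same_rows_twice_identical_scores(self):
        s1, _ = predict(self.model, self.X)
        s2, _ = predict(self.model, self.X)
        assert np.array_equal(s1, s2)

    def test_schema_mismatch_lists_difference(self):
        bad = self.X.rename(columns={"drug__persistence": "other"})
        with pytest.raises(ValueError, match="drug__persistence"):
            predict(self.model, bad)

    def test_column_order_does_not_matter(self):
        s1, _ = predict(self.model, self.X)
        s2, _ = predict(self.model, self.X[list(reversed(self.X.columns))])
        assert np.array_equal(s1, s2)

    def test_roundtrip_serialization(self, tmp_path):
        path = tmp_path / "model.joblib"
        save_model(self.model, path)
        loaded = load_model(path)
        assert np.array_equal(predict(loaded, self.X)[0], predict(self.model, self.X)[0])


class TestFeatureImportance:
    def test_informative_feature_ranks_first(self):
        X, y = separable_frame(n=80)
        model = train_model(X, y, tiny_config("random_forest"))
        ranked = feature_importance(model, X, y, seed=1)
        assert ranked[0][0] == "drug__strength"
        assert ranked[0][1] >= ranked[-1][1]

    def test_pure_noise_feature_never_beats_signal(self):
        rng = np.random.default_rng(11)
        n = 120
        y = np.arange(n) % 2
        X = pd.DataFrame(
            {"signal": y + rng.normal(0, 0.3, n), "noise": rng.normal(size=n)}
        )
        model = train_model(X, y, tiny_config("xgboost"))
        ranked = dict(feature_importance(model, X, y, seed=2))
        assert ranked["noise"] <= ranked["signal"]
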