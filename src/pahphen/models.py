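"""Classifier training, prediction and feature importance.

Three model families are supported — random forest, extreme gradient
boosting (XGBoost) and the elastic net (logistic regression with a mixed
L1/L2 penalty) — mirroring standard practice for coded-EMR phenotyping.
Hyperparameters are chosen by Bayesian optimization (:mod:`pahphen._bayes`)
maximizing the mean AUC of stratified k-fold cross-validation repeated r
times (default 10-fold, 3 repeats -> 30 fold-level AUC samples); the final
model is then refit on the entire training set at the optimum.

Feature importance is permutation importance on held-out data — the drop in
AUC when one feature column is shuffled — which is comparable across the
differently scaled strength / persistence / durability components.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from xgboost import XGBClassifier

from pahphen import _bayes
from pahphen.evaluation import auc_score

ALGORITHMS = ("random_forest", "xgboost", "elastic_net")

#: Conventional search bounds per algorithm; every bound is configuration.
DEFAULT_SEARCH_SPACES: dict[str, list[_bayes.Dimension]] = {
    "random_forest": [
        _bayes.Dimension("n_estimators", 200, 1000, kind="int"),
        _bayes.Dimension("max_features", 0.05, 1.0),
        _bayes.Dimension("min_samples_leaf", 1, 20, kind="int"),
    ],
    "xgboost": [
        _bayes.Dimension("learning_rate", 0.01, 0.3),
        _bayes.Dimension("max_depth", 2, 8, kind="int"),
        _bayes.Dimension("n_estimators", 50, 500, kind="int"),
        _bayes.Dimension("subsample", 0.5, 1.0),
    ],
    "elastic_net": [
        _bayes.Dimension("l1_ratio", 0.0, 1.0),
        _bayes.Dimension("lam", 1e-4, 1e1, log=True),
    ],
}


@dataclass(frozen=True)
class TrainingConfig:
    """Cross-validated Bayesian-optimized training settings.

    ``opt_iterations`` counts surrogate-guided evaluations after
    ``opt_initial`` random ones; 0 iterations with 0 initial points skips
    tuning entirely and uses mid-range defaults.
    """

    algorithm: str = "random_forest"
    cv_folds: int = 10
    cv_repeats: int = 3
    opt_iterations: int = 30
    opt_initial: int = 10
    threshold: float = 0.5
    seed: int = 0
    #: per-algorithm override of the search bounds; None -> DEFAULT_SEARCH_SPACES
    search_spaces: Optional[dict[str, list[_bayes.Dimension]]] = None

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}; expected one of {ALGORITHMS}")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.cv_repeats < 1:
            raise ValueError("cv_repeats must be >= 1")
        if not (0 < self.threshold < 1):
            raise ValueError("threshold must lie in (0, 1)")

    @property
    def space(self) -> list[_bayes.Dimension]:
        return (self.search_spaces or DEFAULT_SEARCH_SPACES)[self.algorithm]


@dataclass
class FittedModel:
    """A tuned, fully refit classifier plus its CV diagnostics."""

    algorithm: str
    params: dict[str, float]
    estimator: object
    columns: list[str]
    cv_auc_samples: list[float]
    threshold: float
    seed: int
    format_version: int = 1

    @property
    def cv_mean_auc(self) -> float:
        return float(np.mean(self.cv_auc_samples))

    def diagnostics(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "params": self.params,
            "cv_auc_samples": list(self.cv_auc_samples),
            "cv_mean_auc": self.cv_mean_auc,
            "threshold": self.threshold,
            "seed": self.seed,
        }


def _build_estimator(algorithm: str, params: dict[str, float], seed: int):
    if algorithm == "random_forest":
        return RandomForestClassifier(
            n_estimators=int(params.get("n_estimators", 500)),
            max_features=float(params.get("max_features", 0.33)),
            min_samples_leaf=int(params.get("min_samples_leaf", 1)),
            random_state=seed,
            n_jobs=1,
        )
    if algorithm == "xgboost":
        return XGBClassifier(
            learning_rate=float(params.get("learning_rate", 0.1)),
            max_depth=int(params.get("max_depth", 4)),
            n_estimators=int(params.get("n_estimators", 200)),
            subsample=float(params.get("subsample", 0.9)),
            tree_method="hist",
            n_jobs=1,
            random_state=seed,
            eval_metric="logloss",
            verbosity=0,
        )
    if algorithm == "elastic_net":
        lam = float(params.get("lam", 1e-2))
        return Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "logit",
                    LogisticRegression(
                        solver="saga",
                        l1_ratio=float(params.get("l1_ratio", 0.5)),
                        C=1.0 / lam,
                        max_iter=500,
                        tol=1e-3,
                        random_state=seed,
                    ),
                ),
            ]
        )
    raise ValueError(f"unknown algorithm {algorithm!r}")


def _as_binary(labels: Sequence) -> np.ndarray:
    y = np.asarray(labels)
    if y.dtype.kind in ("U", "S", "O"):
        y = np.asarray([str(v) == "PAH" for v in y])
    return y.astype(int)


def _cv_fold_aucs(
    estimator, X: np.ndarray, y: np.ndarray, folds: int, repeats: int, seed: int
) -> list[float]:
    cv = RepeatedStratifiedKFold(n_splits=folds, n_repeats=repeats, random_state=seed)
    aucs = []
    for train_idx, test_idx in cv.split(X, y):
        est = clone(estimator)
        est.fit(X[train_idx], y[train_idx])
        scores = est.predict_proba(X[test_idx])[:, 1]
        aucs.append(auc_score(scores, y[test_idx]))
    return aucs


def train_model(
    features: pd.DataFrame, labels: Sequence, config: TrainingConfig
) -> FittedModel:
    """Tune, cross-validate and refit one classifier.

    ``features`` rows must align 1:1 with ``labels``; both classes must be
    present.  Deterministic given ``config.seed``.
    """
    y = _as_binary(labels)
    if len(features) != len(y):
        raise ValueError(f"{len(features)} feature rows but {len(y)} labels")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class; both are required")
    X = features.to_numpy(dtype=float)
    columns = list(features.columns)
    folds = min(config.cv_folds, int(np.bincount(y).min()))
    if folds < 2:
        raise ValueError("minority class too small for stratified cross-validation")

    def objective(params: dict[str, float]) -> float:
        est = _build_estimator(config.algorithm, params, config.seed)
        return float(
            np.mean(_cv_fold_aucs(est, X, y, folds, config.cv_repeats, config.seed))
        )

    if config.opt_iterations == 0 and config.opt_initial == 0:
        best_params: dict[str, float] = {}
    else:
        rng = np.random.default_rng(config.seed)
        best_params, _, _ = _bayes.maximize(
            objective,
            config.space,
            n_initial=config.opt_initial,
            n_iter=config.opt_iterations,
            rng=rng,
        )

    estimator = _build_estimator(config.algorithm, best_params, config.seed)
    cv_samples = _cv_fold_aucs(estimator, X, y, folds, config.cv_repeats, config.seed)
    estimator.fit(X, y)
    return FittedModel(
        algorithm=config.algorithm,
        params=best_params,
        estimator=estimator,
        columns=columns,
        cv_auc_samples=cv_samples,
        threshold=config.threshold,
        seed=config.seed,
    )


def predict(
    model: FittedModel, features: pd.DataFrame, threshold: Optional[float] = None
) -> tuple[np.ndarray, np.ndarray]:
    """Probability-like scores in [0,1] and thresholded labels per row.

    Columns are matched by name against the training column order; a
    missing or extra column is a schema error naming the difference.
    """
    have, want = set(features.columns), set(model.columns)
    if have != want:
        missing = sorted(want - have)
        extra = sorted(have - want)
        raise ValueError(f"feature schema mismatch: missing={missing} extra={extra}")
    thr = model.threshold if threshold is None else threshold
    X = features[model.columns].to_numpy(dtype=float)
    if len(X) == 0:
        return np.zeros(0), np.zeros(0, dtype=bool)
    scores = model.estimator.predict_proba(X)[:, 1]
    return scores, scores >= thr


def feature_importance(
    model: FittedModel,
    features: pd.DataFrame,
    labels: Sequence,
    n_repeats: int = 5,
    seed: int = 0,
) -> list[tuple[str, float]]:
    """Permutation importance: mean AUC drop when a column is shuffled.

    Computed on held-out data (pass the stage test set), sorted by
    importance descending with ties broken by feature name; deterministic
    given ``seed``.
    """
    y = _as_binary(labels)
    scores, _ = predict(model, features)
    baseline = auc_score(scores, y)
    rng = np.random.default_rng(seed)
    X = features[model.columns].to_numpy(dtype=float)
    drops: list[tuple[str, float]] = []
    for j, name in enumerate(model.columns):
        total = 0.0
        for _ in range(n_repeats):
            Xp = X.copy()
            Xp[:, j] = Xp[rng.permutation(len(Xp)), j]
            s = model.estimator.predict_proba(Xp)[:, 1]
            total += baseline - auc_score(s, y)
        drops.append((name, total / n_repeats))
    drops.sort(key=lambda t: (-t[1], t[0]))
    return drops


def save_model(model: FittedModel, path) -> None:
    joblib.dump(model, path)


def load_model(path) -> FittedModel:
    model = joblib.load(path)
    if not isinstance(model, FittedModel):
        raise ValueError(f"{path} does not contain a FittedModel")
    return model


def with_seed(config: TrainingConfig, seed: int) -> TrainingConfig:
    return replace(config, seed=seed)


def desk_scale_config(seed: int = 0, threshold: float = 0.5) -> TrainingConfig:
    """Training settings sized for desk-scale simulation studies.

    Cross-validation is 3-fold single-repeat and the Bayesian search runs
    3 random + 2 guided evaluations over reduced bounds (forests of
    100-300 trees, boosters of 30-150 rounds), which is ample for the
    strongly separable planted-signal cohorts the synthetic generator
    produces while keeping a full multi-stage run to a couple of minutes
    on one CPU.  Full-scale studies should use the TrainingConfig defaults.
    """
    return TrainingConfig(
        cv_folds=3,
        cv_repeats=1,
        opt_iterations=2,
        opt_initial=3,
        threshold=threshold,
        seed=seed,
        search_spaces=DESK_SCALE_SEARCH_SPACES,
    )


DESK_SCALE_SEARCH_SPACES: dict[str, list[_bayes.Dimension]] = {
    "random_forest": [
        _bayes.Dimension("n_estimators", 100, 300, kind="int"),
        _bayes.Dimension("max_features", 0.05, 1.0),
        _bayes.Dimension("min_samples_leaf", 1, 20, kind="int"),
    ],
    "xgboost": [
        _bayes.Dimension("learning_rate", 0.03, 0.3),
        _bayes.Dimension("max_depth", 2, 6, kind="int"),
        _bayes.Dimension("n_estimators", 30, 150, kind="int"),
        _bayes.Dimension("subsample", 0.5, 1.0),
    ],
    "elastic_net": [
        _bayes.Dimension("l1_ratio", 0.0, 1.0),
        _bayes.Dimension("lam", 1e-3, 1e1, log=True),
    ],
}
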