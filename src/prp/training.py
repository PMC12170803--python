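"""Classifier tuning and fitting on the labeled feature matrix.

Four pluggable algorithm families are exposed behind one interface:
``gbt_xgb_style`` (XGBoost), ``gbt_hist_style`` (LightGBM),
``gbt_ordered_style`` (scikit-learn histogram gradient boosting) and
``mlp`` (scikit-learn multilayer perceptron). Hyperparameters are tuned
with a seeded TPE sampler and median pruner over stratified k-fold
cross-validation maximizing AUC; the preprocessor (imputation +
normalization) is refit inside every training fold so no validation
information leaks into the fit.
"""

from __future__ import annotations

import pickle
import hashlib
import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from prp.evaluation import roc_auc
from prp.features import (
    PreprocessingModel,
    apply_preprocessor,
    fit_preprocessor,
)
from prp.tpe import (
    Categorical,
    IntUniform,
    LogUniform,
    MedianPruner,
    TPESampler,
    Uniform,
    validate_space,
)

logger = logging.getLogger(__name__)

ALGORITHMS = ("gbt_xgb_style", "gbt_hist_style", "gbt_ordered_style", "mlp")


def _predict_proba(estimator, X: np.ndarray) -> np.ndarray:
    """predict_proba with a known upstream nuisance warning silenced.

    LightGBM's sklearn wrapper warns about feature names at predict time
    even when both fit and predict receive plain arrays.
    """
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="X does not have valid feature names"
        )
        return estimator.predict_proba(X)


@dataclass
class AlgorithmSpec:
    """An algorithm id plus its hyperparameter search space."""

    algorithm_id: str
    space: dict
    fixed: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.algorithm_id not in ALGORITHMS:
            raise ValueError(
                f"unknown algorithm {self.algorithm_id!r}; expected {ALGORITHMS}"
            )
        validate_space(self.space)


def default_search_space(algorithm_id: str, scale: str = "full") -> dict:
    """Default search space per algorithm.

    ``scale='full'`` follows the protocol-size ranges (learning rate
    log-uniform [1e-3, 0.3], depth 3–12, 100–2000 estimators);
    ``scale='desk'`` shrinks the tree count for desk-scale runs.
    """
    n_lo, n_hi = (100, 2000) if scale == "full" else (50, 300)
    d_hi = 12 if scale == "full" else 8
    if algorithm_id in ("gbt_xgb_style", "gbt_hist_style"):
        space = {
            "learning_rate": LogUniform(1e-3, 0.3),
            "max_depth": IntUniform(3, d_hi),
            "n_estimators": IntUniform(n_lo, n_hi),
            "subsample": Uniform(0.5, 1.0),
            "colsample": Uniform(0.5, 1.0),
            "reg_lambda": LogUniform(1e-3, 10.0),
        }
        if algorithm_id == "gbt_xgb_style":
            space["min_child_weight"] = LogUniform(0.1, 10.0)
        else:
            space["min_child_samples"] = IntUniform(5, 100)
        return space
    if algorithm_id == "gbt_ordered_style":
        return {
            "learning_rate": LogUniform(1e-3, 0.3),
            "max_depth": IntUniform(3, d_hi),
            "n_estimators": IntUniform(n_lo, n_hi),
            "reg_lambda": LogUniform(1e-3, 10.0),
        }
    if algorithm_id == "mlp":
        return {
            "n_layers": IntUniform(1, 3),
            "units1": Categorical((16, 32, 64, 128, 256)),
            "units2": Categorical((16, 32, 64, 128, 256), condition=("n_layers", (2, 3))),
            "units3": Categorical((16, 32, 64, 128, 256), condition=("n_layers", (3,))),
            "learning_rate_init": LogUniform(1e-4, 1e-2),
            "alpha": LogUniform(1e-6, 1e-2),
        }
    raise ValueError(f"unknown algorithm {algorithm_id!r}")


def default_spec(algorithm_id: str, seed: int = 0, scale: str = "full") -> AlgorithmSpec:
    return AlgorithmSpec(
        algorithm_id=algorithm_id,
        space=default_search_space(algorithm_id, scale),
        seed=seed,
    )


def make_estimator(algorithm_id: str, params: dict, seed: int = 0):
    """Instantiate the backing classifier with mapped hyperparameters."""
    params = dict(params)
    if algorithm_id == "gbt_xgb_style":
        from xgboost import XGBClassifier

        params["colsample_bytree"] = params.pop("colsample", 1.0)
        return XGBClassifier(
            **params,
            random_state=seed,
            n_jobs=1,
            tree_method="hist",
            eval_metric="logloss",
            verbosity=0,
        )
    if algorithm_id == "gbt_hist_style":
        from lightgbm import LGBMClassifier

        params["colsample_bytree"] = params.pop("colsample", 1.0)
        if params.get("subsample", 1.0) < 1.0:
            params["subsample_freq"] = 1
        return LGBMClassifier(
            **params, random_state=seed, n_jobs=1, verbose=-1
        )
    if algorithm_id == "gbt_ordered_style":
        from sklearn.ensemble import HistGradientBoostingClassifier

        return HistGradientBoostingClassifier(
            learning_rate=params.get("learning_rate", 0.1),
            max_depth=params.get("max_depth"),
            max_iter=params.get("n_estimators", 100),
            l2_regularization=params.get("reg_lambda", 0.0),
            random_state=seed,
        )
    if algorithm_id == "mlp":
        from sklearn.neural_network import MLPClassifier

        n_layers = params.get("n_layers", 1)
        layers = tuple(
            params.get(f"units{i}", 64) for i in range(1, n_layers + 1)
        )
        return MLPClassifier(
            hidden_layer_sizes=layers,
            learning_rate_init=params.get("learning_rate_init", 1e-3),
            alpha=params.get("alpha", 1e-4),
            max_iter=params.get("max_iter", 300),
            random_state=seed,
        )
    raise ValueError(f"unknown algorithm {algorithm_id!r}")


def stratified_kfold(labels: Sequence[int], k: int, seed: int = 0) -> list:
    """k disjoint, class-balanced validation index sets (deterministic)."""
    labels = np.asarray(labels, dtype=int)
    if k < 2:
        raise ValueError("k must be >= 2")
    for cls in np.unique(labels):
        if np.sum(labels == cls) < k:
            raise ValueError(f"class {cls} has fewer than k={k} members")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [val_idx for _, val_idx in skf.split(np.zeros(len(labels)), labels)]


def cv_score(
    algorithm_spec: AlgorithmSpec,
    params: dict,
    feature_table: pd.DataFrame,
    labels: Sequence[int],
    folds: list,
    pruner: Optional[MedianPruner] = None,
) -> tuple:
    """Mean held-out AUC over folds (leakage-free preprocessing).

    Returns ``(mean_auc, fold_aucs, pruned, running_means)``. The
    preprocessor is fit on
    each training fold only. A degenerate fold with one class contributes
    a missing AUC and a warning; the mean runs over the remaining folds.
    When a pruner is supplied, the trial may stop early after any fold.
    """
    labels = np.asarray(labels, dtype=int)
    all_idx = np.arange(len(labels))
    fold_aucs: list = []
    running_means: list = []
    pruned = False
    for step, val_idx in enumerate(folds):
        train_idx = np.setdiff1d(all_idx, val_idx)
        X_train = feature_table.iloc[train_idx]
        X_val = feature_table.iloc[val_idx]
        prep = fit_preprocessor(X_train)
        est = make_estimator(
            algorithm_spec.algorithm_id,
            {**algorithm_spec.fixed, **params},
            seed=algorithm_spec.seed,
        )
        est.fit(apply_preprocessor(prep, X_train).to_numpy(), labels[train_idx])
        scores = _predict_proba(est, apply_preprocessor(prep, X_val).to_numpy())[:, 1]
        y_val = labels[val_idx]
        if len(np.unique(y_val)) < 2:
            warnings.warn(f"fold {step}: single-class validation fold, AUC missing")
            fold_aucs.append(None)
        else:
            fold_aucs.append(roc_auc(scores, y_val))
        valid = [a for a in fold_aucs if a is not None]
        running = float(np.mean(valid)) if valid else 0.0
        running_means.append(running)
        if pruner is not None and step < len(folds) - 1:
            if pruner.should_prune(step, running):
                pruned = True
                break
    valid = [a for a in fold_aucs if a is not None]
    mean_auc = float(np.mean(valid)) if valid else None
    return mean_auc, fold_aucs, pruned, running_means


@dataclass
class TrialResult:
    index: int
    params: dict
    fold_aucs: list
    mean_auc: Optional[float]
    pruned: bool


@dataclass
class TuneResult:
    best_params: dict
    best_auc: Optional[float]
    trials: list


def tune(
    algorithm_spec: AlgorithmSpec,
    feature_table: pd.DataFrame,
    labels: Sequence[int],
    n_trials: int = 100,
    seed: int = 0,
    k: int = 10,
    n_startup: int = 10,
) -> TuneResult:
    """TPE search with median pruning over stratified k-fold CV AUC."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    folds = stratified_kfold(labels, k, seed)
    sampler = TPESampler(algorithm_spec.space, seed=seed, n_startup=n_startup)
    pruner = MedianPruner()
    history: list = []
    trials: list = []
    for t in range(n_trials):
        params = sampler.suggest(history)
        mean_auc, fold_aucs, pruned, running = cv_score(
            algorithm_spec, params, feature_table, labels, folds, pruner=pruner
        )
        trials.append(TrialResult(t, params, fold_aucs, mean_auc, pruned))
        history.append((params, mean_auc))
        if not pruned:
            pruner.report_completed(running)
        logger.info(
            "trial %d: auc=%s pruned=%s params=%s", t, mean_auc, pruned, params
        )
    completed = [tr for tr in trials if not tr.pruned and tr.mean_auc is not None]
    if completed:
        best = max(completed, key=lambda tr: tr.mean_auc)
    else:
        warnings.warn("all trials pruned; returning best partial score")
        best = max(
            (tr for tr in trials if tr.mean_auc is not None),
            key=lambda tr: tr.mean_auc,
        )
    return TuneResult(best_params=best.params, best_auc=best.mean_auc, trials=trials)


@dataclass
class TrainedModel:
    """A fitted classifier plus everything needed to reproduce predictions."""

    algorithm_id: str
    params: dict
    estimator: object
    preprocessor: PreprocessingModel
    feature_names: tuple
    threshold: float = 0.5
    fingerprint: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0,1)")

    def save(self, path):
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path) -> "TrainedModel":
        with open(path, "rb") as fh:
            model = pickle.load(fh)
        if not isinstance(model, TrainedModel):
            raise TypeError(f"{path} is not a TrainedModel artifact")
        return model


def _data_hash(feature_table: pd.DataFrame, labels) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(feature_table.to_numpy(dtype=float)).tobytes())
    h.update(np.asarray(labels, dtype=int).tobytes())
    return h.hexdigest()[:16]


def fit_final(
    algorithm_spec: AlgorithmSpec,
    best_params: dict,
    feature_table: pd.DataFrame,
    labels: Sequence[int],
    threshold: float = 0.5,
) -> TrainedModel:
    """Refit the preprocessor and classifier on the full training table."""
    labels = np.asarray(labels, dtype=int)
    prep = fit_preprocessor(feature_table)
    est = make_estimator(
        algorithm_spec.algorithm_id,
        {**algorithm_spec.fixed, **best_params},
        seed=algorithm_spec.seed,
    )
    est.fit(apply_preprocessor(prep, feature_table).to_numpy(), labels)
    return TrainedModel(
        algorithm_id=algorithm_spec.algorithm_id,
        params=dict(best_params),
        estimator=est,
        preprocessor=prep,
        feature_names=tuple(feature_table.columns),
        threshold=threshold,
        fingerprint={
            "seed": algorithm_spec.seed,
            "data_hash": _data_hash(feature_table, labels),
            "cv": "stratified-kfold",
        },
    )


def predict(model: TrainedModel, feature_table: pd.DataFrame) -> np.ndarray:
    """Pathogenicity scores in [0,1] for raw (unpreprocessed) features."""
    if tuple(feature_table.columns) != model.feature_names:
        raise ValueError(
            "feature schema mismatch: model was trained on "
            f"{len(model.feature_names)} features "
            f"{list(model.feature_names[:3])}..., got "
            f"{len(feature_table.columns)} columns"
        )
    X = apply_preprocessor(model.preprocessor, feature_table).to_numpy()
    scores = _predict_proba(model.estimator, X)[:, 1]
    return np.clip(scores, 0.0, 1.0)


def classify(scores: Sequence[float], threshold: float = 0.5) -> np.ndarray:
    """Binary labels: pathogenic iff score >= threshold."""
    return (np.asarray(scores, dtype=float) >= threshold).astype(int)
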