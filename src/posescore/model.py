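"""Gradient-boosted pose classification/regression with seeded tuning.

The training protocol: drop features whose training-set variance is below
0.01, standardize the survivors, then fit an XGBoost model whose
hyperparameters are selected by mean AUROC (classification) or RMSE
(regression) over a 5-fold cross-validation *grouped by complex*, so no
complex contributes poses to both sides of a tuning fold.  Search is a
seeded random sampler over a declared space (60 evaluations by default);
the sampled configurations and their scores are kept as an auditable
tuning history.  Seeds default to 2399 (model) and 123 (tuner).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GroupKFold
from xgboost import XGBClassifier, XGBRegressor

from .features import ID_COLUMNS, feature_columns

__all__ = [
    "Preprocessor", "TrainedModel",
    "fit_preprocessor", "tune_and_train", "train_regressor", "predict",
    "save_model", "load_model",
    "VARIANCE_THRESHOLD", "DEFAULT_MODEL_SEED", "DEFAULT_TUNER_SEED",
    "SEARCH_SPACE",
]

VARIANCE_THRESHOLD = 0.01      # features with variance strictly below are dropped
DEFAULT_MODEL_SEED = 2399
DEFAULT_TUNER_SEED = 123


@dataclass
class Preprocessor:
    """Variance filter + standardization, fitted on training rows only."""

    kept: list[str]
    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, table: pd.DataFrame,
            threshold: float = VARIANCE_THRESHOLD) -> "Preprocessor":
        if len(table) < 2:
            raise ValueError("need at least 2 training rows")
        cols = feature_columns(table)
        X = table[cols].to_numpy(dtype=float)
        var = np.nanvar(X, axis=0)
        keep = var >= threshold   # strict "< threshold" is dropped
        if not keep.any():
            raise ValueError("variance filter removed every feature")
        kept = [c for c, k in zip(cols, keep) if k]
        Xk = X[:, keep]
        mean = np.nanmean(Xk, axis=0)
        sd = np.nanstd(Xk, axis=0)
        sd[sd == 0] = 1.0
        return cls(kept=kept, mean=mean, sd=sd)

    def transform(self, table: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.kept if c not in table.columns]
        if missing:
            raise ValueError(f"rows are missing feature columns: {missing[:5]}"
                             + ("..." if len(missing) > 5 else ""))
        X = table[self.kept].to_numpy(dtype=float)
        return (X - self.mean) / self.sd


def fit_preprocessor(train_rows: pd.DataFrame,
                     threshold: float = VARIANCE_THRESHOLD) -> Preprocessor:
    return Preprocessor.fit(train_rows, threshold)


# declared hyperparameter search space; each entry draws from the seeded rng
SEARCH_SPACE = {
    "max_depth": lambda rng: int(rng.integers(3, 11)),
    "learning_rate": lambda rng: float(10 ** rng.uniform(-3, -0.5)),
    "n_estimators": lambda rng: int(rng.integers(100, 1001)),
    "subsample": lambda rng: float(rng.uniform(0.5, 1.0)),
    "colsample_bytree": lambda rng: float(rng.uniform(0.5, 1.0)),
    "min_child_weight": lambda rng: int(rng.integers(1, 11)),
    "gamma": lambda rng: float(rng.uniform(0.0, 5.0)),
    "reg_lambda": lambda rng: float(10 ** rng.uniform(-2, 1)),
}


def _sample_params(rng: np.random.Generator) -> dict:
    return {name: draw(rng) for name, draw in SEARCH_SPACE.items()}


def _make_estimator(task: str, params: dict, model_seed: int):
    common = dict(random_state=model_seed, n_jobs=1, tree_method="hist",
                  verbosity=0, **params)
    if task == "classify":
        return XGBClassifier(eval_metric="logloss", **common)
    return XGBRegressor(**common)


@dataclass
class TrainedModel:
    estimator: object
    preprocessor: Preprocessor
    params: dict
    history: pd.DataFrame
    model_seed: int
    tuner_seed: int
    task: str                      # classify | regress
    uses_rank: bool

    def serialized_booster(self) -> bytes:
        return bytes(self.estimator.get_booster().save_raw("json"))


def _target(table: pd.DataFrame, task: str) -> np.ndarray:
    col = "label" if task == "classify" else "rmsd"
    return table[col].to_numpy(dtype=float)


def _cv_score(table: pd.DataFrame, params: dict, task: str, cv_folds: int,
              model_seed: int) -> float:
    """Mean grouped-CV AUROC (classify) or negative RMSE (regress)."""
    groups = table["complex_id"].to_numpy()
    y_all = _target(table, task)
    gkf = GroupKFold(n_splits=cv_folds)
    scores = []
    for tr_idx, te_idx in gkf.split(table, y_all, groups):
        tr, te = table.iloc[tr_idx], table.iloc[te_idx]
        if task == "classify" and len(np.unique(_target(te, task))) < 2:
            continue
        prep = Preprocessor.fit(tr)
        est = _make_estimator(task, params, model_seed)
        est.fit(prep.transform(tr), _target(tr, task))
        if task == "classify":
            pred = est.predict_proba(prep.transform(te))[:, 1]
            scores.append(roc_auc_score(_target(te, task), pred))
        else:
            pred = est.predict(prep.transform(te))
            scores.append(-float(np.sqrt(np.mean((pred - _target(te, task)) ** 2))))
    if not scores:
        raise ValueError("no evaluable CV fold (single-class folds everywhere)")
    return float(np.mean(scores))


def tune_and_train(train_rows: pd.DataFrame, task: str = "classify",
                   max_evals: int = 60, cv_folds: int = 5,
                   model_seed: int = DEFAULT_MODEL_SEED,
                   tuner_seed: int = DEFAULT_TUNER_SEED) -> TrainedModel:
    """Hyperparameter search + final refit on all training rows.

    Raises on single-class training data (classification) or when fewer
    distinct complexes than CV folds are available.
    """
    if task not in ("classify", "regress"):
        raise ValueError(f"unknown task: {task!r}")
    y = _target(train_rows, task)
    if task == "classify" and len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")
    n_groups = train_rows["complex_id"].nunique()
    if n_groups < cv_folds:
        raise ValueError(f"{n_groups} complexes < {cv_folds} CV folds")

    rng = np.random.default_rng(tuner_seed)
    history_rows = []
    best_score, best_params = -np.inf, None
    for it in range(max_evals):
        params = _sample_params(rng)
        if max_evals == 1:
            score = np.nan   # single configuration: no search
        else:
            score = _cv_score(train_rows, params, task, cv_folds, model_seed)
        history_rows.append({"iteration": it, "score": score, **params})
        if max_evals == 1 or score > best_score:
            best_score, best_params = score, params

    prep = Preprocessor.fit(train_rows)
    est = _make_estimator(task, best_params, model_seed)
    est.fit(prep.transform(train_rows), y)
    uses_rank = "RANK::dock_rank" in prep.kept
    return TrainedModel(estimator=est, preprocessor=prep, params=best_params,
                        history=pd.DataFrame(history_rows), model_seed=model_seed,
                        tuner_seed=tuner_seed, task=task, uses_rank=uses_rank)


def train_regressor(train_rows: pd.DataFrame, max_evals: int = 60,
                    cv_folds: int = 5, model_seed: int = DEFAULT_MODEL_SEED,
                    tuner_seed: int = DEFAULT_TUNER_SEED) -> TrainedModel:
    """RMSD regressor trained with the same protocol, RMSE-selected."""
    return tune_and_train(train_rows, task="regress", max_evals=max_evals,
                          cv_folds=cv_folds, model_seed=model_seed,
                          tuner_seed=tuner_seed)


def predict(model: TrainedModel, rows: pd.DataFrame) -> np.ndarray:
    """Scores for new pose rows: P(near-native) or predicted RMSD (>= 0 A).

    A rank-using model refuses rows whose rank feature is missing.
    """
    if model.uses_rank and "RANK::dock_rank" in rows.columns:
        if rows["RANK::dock_rank"].isna().any():
            raise ValueError(
                "model uses the docking-rank feature but some rows have no "
                "rank; rescore these sets with a rank-free model")
    X = model.preprocessor.transform(rows)
    if model.task == "classify":
        return model.estimator.predict_proba(X)[:, 1]
    return np.clip(model.estimator.predict(X), 0.0, None)


def save_model(model: TrainedModel, path: str | Path) -> None:
    joblib.dump(model, path)


def load_model(path: str | Path) -> TrainedModel:
    return joblib.load(path)
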