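"""Ensemble classifiers for show-up prediction with cross-validated tuning.

Three algorithms are supported — Random Forest (RF), Gradient Boosting (GB)
and AdaBoost (AB) — each with its conventional hyperparameter grid: trees,
max features, depth and min split samples for RF; trees, learning rate, depth
and subsample fraction for GB; trees and learning rate for AB.  Tuning is an
exhaustive grid search scored by stratified k-fold cross-validation with a
deterministic first-in-enumeration-order tie break.  Categorical covariates
(department, residence zone, season) are one-hot encoded with fixed category
lists; binaries and age pass through unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.compose import ColumnTransformer
from sklearn.ensemble import (
    AdaBoostClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.model_selection import ParameterGrid, StratifiedKFold, cross_val_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import OneHotEncoder

from noshowpricing.cohort import BINARY_COVARIATES, DEPARTMENTS, SEASONS, season_of
from noshowpricing.io import outcome_to_binary

__all__ = [
    "ALGORITHMS",
    "ALLOWED_GRID_KEYS",
    "DEFAULT_GRIDS",
    "ModelSpec",
    "SplitConfig",
    "PredictionSet",
    "TuningResult",
    "EncodingError",
    "stratified_split",
    "tune_model",
    "fit_predict",
]

logger = logging.getLogger(__name__)

ALGORITHMS = ("RF", "GB", "AB")

ALLOWED_GRID_KEYS = {
    "RF": frozenset({"n_estimators", "max_features", "max_depth", "min_samples_split"}),
    "GB": frozenset({"n_estimators", "learning_rate", "max_depth", "subsample"}),
    "AB": frozenset({"n_estimators", "learning_rate"}),
}

DEFAULT_GRIDS = {
    "RF": {
        "n_estimators": [100, 300, 500],
        "max_features": ["sqrt", "log2"],
        "max_depth": [None, 5, 10],
        "min_samples_split": [2, 5, 10],
    },
    "GB": {
        "n_estimators": [100, 300],
        "learning_rate": [0.01, 0.1, 0.3],
        "max_depth": [2, 3, 5],
        "subsample": [0.7, 1.0],
    },
    "AB": {
        "n_estimators": [50, 100, 300],
        "learning_rate": [0.5, 1.0],
    },
}

_FEATURE_BINARIES = list(BINARY_COVARIATES) + ["weekend_flag"]


class EncodingError(ValueError):
    """A categorical level outside the fixed vocabulary was met at encode time."""


@dataclass(frozen=True)
class ModelSpec:
    """Algorithm choice, hyperparameter grid and cross-validation settings."""

    algorithm: str
    grid: dict[str, list] | None = None
    cv_folds: int = 5
    scoring: str = "accuracy"  # classification accuracy; "roc_auc" also supported
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}, got {self.algorithm!r}")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        grid = self.grid if self.grid is not None else DEFAULT_GRIDS[self.algorithm]
        bad = set(grid) - ALLOWED_GRID_KEYS[self.algorithm]
        if bad:
            raise ValueError(
                f"grid keys {sorted(bad)} not tunable for {self.algorithm}; "
                f"allowed: {sorted(ALLOWED_GRID_KEYS[self.algorithm])}"
            )
        if not grid or any(len(v) == 0 for v in grid.values()):
            raise ValueError("grid must be non-empty")
        object.__setattr__(self, "grid", {k: list(v) for k, v in grid.items()})


@dataclass(frozen=True)
class SplitConfig:
    """Train/test split: fraction held out, stratification on outcome, seed."""

    test_fraction: float = 0.3
    stratify: bool = True
    seed: int = 42

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class PredictionSet:
    """Actual labels, predicted labels and show-up scores for one phase."""

    phase: str
    actual: np.ndarray
    predicted: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.actual) == len(self.predicted) == len(self.scores)):
            raise ValueError("actual, predicted and scores must have equal length")
        if (self.scores < 0).any() or (self.scores > 1).any():
            raise ValueError("scores must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "row_id": np.arange(len(self.actual)),
                "phase": self.phase,
                "actual": self.actual,
                "predicted": self.predicted,
                "score": self.scores,
            }
        )


@dataclass(frozen=True)
class TuningResult:
    """Winning hyperparameters plus the full per-fold CV score table."""

    algorithm: str
    best_params: dict
    best_score: float
    cv_table: pd.DataFrame = field(repr=False)


def stratified_split(
    cohort: pd.DataFrame, split: SplitConfig = SplitConfig()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Deterministic train/test split, stratified on the outcome by default."""
    y = outcome_to_binary(cohort["outcome"])
    if len(np.unique(y)) < 2:
        raise ValueError("cohort must contain both outcome classes")
    rng = np.random.default_rng(split.seed)
    n = len(cohort)
    n_test = round(n * split.test_fraction)
    if split.stratify:
        test_idx: list[int] = []
        for cls in (0, 1):
            cls_idx = np.flatnonzero(y == cls)
            n_cls_test = round(len(cls_idx) * split.test_fraction)
            test_idx.extend(rng.permutation(cls_idx)[:n_cls_test])
        test_mask = np.zeros(n, dtype=bool)
        test_mask[test_idx] = True
    else:
        test_mask = np.zeros(n, dtype=bool)
        test_mask[rng.permutation(n)[:n_test]] = True
    train = cohort.loc[~test_mask].reset_index(drop=True)
    test = cohort.loc[test_mask].reset_index(drop=True)
    return train, test


def _feature_frame(cohort: pd.DataFrame) -> pd.DataFrame:
    X = cohort[_FEATURE_BINARIES + ["age", "department", "location_id"]].copy()
    X["season"] = season_of(cohort["date"]).to_numpy()
    return X


def make_estimator(spec: ModelSpec, params: dict | None = None, n_locations: int = 66) -> Pipeline:
    """Preprocessing + classifier pipeline for one algorithm."""
    if spec.algorithm == "RF":
        clf = RandomForestClassifier(random_state=spec.seed)
    elif spec.algorithm == "GB":
        clf = GradientBoostingClassifier(random_state=spec.seed)
    else:
        clf = AdaBoostClassifier(random_state=spec.seed)
    if params:
        clf.set_params(**params)
    encoder = OneHotEncoder(
        categories=[list(DEPARTMENTS), list(range(n_locations)), list(SEASONS)],
        handle_unknown="error",
        sparse_output=False,
    )
    pre = ColumnTransformer(
        [("onehot", encoder, ["department", "location_id", "season"])],
        remainder="passthrough",
    )
    return Pipeline([("encode", pre), ("classify", clf)])


def tune_model(
    spec: ModelSpec, train: pd.DataFrame, n_locations: int = 66
) -> TuningResult:
    """Exhaustive grid search scored by stratified k-fold cross-validation.

    Configurations whose CV fails on any fold (e.g. a single-class fold) are
    scored NaN, logged and excluded from the argmax.  Ties break to the first
    configuration in grid-enumeration order.
    """
    grid = list(ParameterGrid(spec.grid))
    X = _feature_frame(train)
    y = outcome_to_binary(train["outcome"])
    cv = StratifiedKFold(n_splits=spec.cv_folds, shuffle=True, random_state=spec.seed)

    records = []
    means = []
    for i, params in enumerate(grid):
        est = make_estimator(spec, params, n_locations)
        scores = cross_val_score(
            est, X, y, cv=cv, scoring=spec.scoring, error_score=np.nan
        )
        mean = float(np.mean(scores))  # NaN if any fold failed
        if np.isnan(scores).any():
            logger.warning(
                "%s configuration %d (%r) failed cross-validation; excluded",
                spec.algorithm,
                i,
                params,
            )
            mean = float("nan")
        records.append(
            {
                "config_index": i,
                **{f"param_{k}": v for k, v in params.items()},
                **{f"fold{j}_score": s for j, s in enumerate(scores)},
                "mean_score": mean,
            }
        )
        means.append(mean)

    means_arr = np.asarray(means)
    if np.isnan(means_arr).all():
        raise RuntimeError("every hyperparameter configuration failed cross-validation")
    best_i = int(np.nanargmax(means_arr))  # first index on ties
    return TuningResult(
        algorithm=spec.algorithm,
        best_params=dict(grid[best_i]),
        best_score=float(means_arr[best_i]),
        cv_table=pd.DataFrame.from_records(records),
    )


def fit_predict(
    spec: ModelSpec,
    best_params: dict,
    train: pd.DataFrame,
    test: pd.DataFrame,
    n_locations: int = 66,
) -> dict[str, PredictionSet]:
    """Fit on the training phase and score both phases.

    Scores are show-up class probabilities; predicted labels are scores
    thresholded at 0.5, so labels and scores are consistent by construction.
    """
    est = make_estimator(spec, best_params, n_locations)
    y_train = outcome_to_binary(train["outcome"])
    try:
        est.fit(_feature_frame(train), y_train)
    except ValueError as exc:  # unseen categorical level, etc.
        raise EncodingError(str(exc)) from exc

    out = {}
    for phase, frame in (("train", train), ("test", test)):
        try:
            scores = est.predict_proba(_feature_frame(frame))[:, 1]
        except ValueError as exc:
            raise EncodingError(f"{phase} phase: {exc}") from exc
        out[phase] = PredictionSet(
            phase=phase,
            actual=outcome_to_binary(frame["outcome"]),
            predicted=(scores >= 0.5).astype(int),
            scores=scores,
        )
    return out
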