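"""Familiarity classification: splits, tuning, evaluation, SHAP ranking.

The binary classifier is gradient-boosted trees (XGBoost) scored by negative
log-likelihood. Two validation schemes are supported: a window-level
stratified 80/20 split, and leave-five-out-for-testing (L5O4T), which holds
out every window of five randomly drawn participants' familiar recordings
and — independently drawn — five participants' unfamiliar recordings, so no
held-out recording leaks into training or cross-validation folds. L5O4T is
repeated (default 10×) with fresh draws; average/best/worst accuracies are
reported. Feature importance is the mean absolute SHAP value per feature,
computed with XGBoost's native TreeSHAP.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedKFold, train_test_split

from .io_formats import METADATA_COLUMNS, FeatureTable

LABELS = {"familiar": 1, "unfamiliar": 0}

#: per-parameter union of the winning configurations across validation
#: schemes and feature sets; the full searched grid is not public.
DEFAULT_GRID: dict[str, list] = {
    "subsample": [0.1, 0.4, 0.5],
    "n_estimators": [100, 500, 700, 1000],
    "min_child_weight": [0.5, 0.6, 0.7],
    "max_depth": [3, 6, 10],
    "learning_rate": [0.001, 0.01, 0.05, 0.1],
    "gamma": [0.6, 0.7, 1.0],
    "colsample_bytree": [0.6, 0.7, 0.8, 1.0],
}

#: single-point grid for calibration experiments where tuning is not the
#: question
FIXED_POINT_GRID: dict[str, list] = {
    "subsample": [0.8],
    "n_estimators": [300],
    "min_child_weight": [1.0],
    "max_depth": [6],
    "learning_rate": [0.1],
    "gamma": [0.0],
    "colsample_bytree": [0.8],
}


@dataclass(frozen=True)
class ModelConfig:
    subsample: float = 0.8
    n_estimators: int = 300
    min_child_weight: float = 1.0
    max_depth: int = 6
    learning_rate: float = 0.1
    gamma: float = 0.0
    colsample_bytree: float = 0.8
    n_cv_folds: int = 10
    seed: int = 0

    def xgb_params(self) -> dict:
        return {
            "subsample": self.subsample,
            "n_estimators": self.n_estimators,
            "min_child_weight": self.min_child_weight,
            "max_depth": self.max_depth,
            "learning_rate": self.learning_rate,
            "gamma": self.gamma,
            "colsample_bytree": self.colsample_bytree,
        }


@dataclass
class SplitPlan:
    scheme: str  # "split_8020" | "l5o4t"
    repeat_index: int
    train_ids: np.ndarray  # row indices into the feature table
    test_ids: np.ndarray
    holdout_participants: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.intersect1d(self.train_ids, self.test_ids).size:
            raise ValueError("train and test rows overlap")


@dataclass
class EvalReport:
    accuracy: float
    confusion: dict[str, float]  # proportions over all test rows, sum to 1
    logloss_train: list[float]  # per boosting round
    logloss_test: list[float]
    config: ModelConfig
    n_test: int = 0

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "confusion": self.confusion,
            "logloss_train": self.logloss_train,
            "logloss_test": self.logloss_test,
            "config": vars(self.config),
            "n_test": self.n_test,
        }


@dataclass
class ImportanceReport:
    ranking: list[dict]  # [{rank, feature, family, mean_abs_shap}]

    def top_feature(self) -> dict:
        return self.ranking[0]

    def to_dict(self) -> dict:
        return {"ranking": self.ranking}


# ---------------------------------------------------------------------------
# outlier filtering


def fit_outlier_stats(df: pd.DataFrame, columns: Sequence[str]):
    """Per-column mean/SD from the training population (NaNs ignored)."""
    sub = df[list(columns)]
    return sub.mean(skipna=True), sub.std(skipna=True, ddof=1)


def apply_outlier_filter(
    df: pd.DataFrame, means: pd.Series, sds: pd.Series, n_sd: float = 3.0
) -> pd.DataFrame:
    """Drop rows containing any value more than ``n_sd`` standard deviations
    from the (training) mean; NaNs never trigger removal."""
    cols = means.index
    z = (df[cols] - means) / sds.replace(0.0, np.nan)
    keep = ~(z.abs() > n_sd).any(axis=1)
    return df.loc[keep]


def filter_outliers(
    df: pd.DataFrame, columns: Sequence[str] | None = None, n_sd: float = 3.0
) -> pd.DataFrame:
    """Self-referential 3-SD filter (stats fit on the same rows)."""
    if columns is None:
        columns = [c for c in df.columns if c not in METADATA_COLUMNS
                   and pd.api.types.is_numeric_dtype(df[c])]
    means, sds = fit_outlier_stats(df, columns)
    return apply_outlier_filter(df, means, sds, n_sd)


# ---------------------------------------------------------------------------
# splits


def make_split(
    table: FeatureTable,
    scheme: str,
    seed: int,
    n_holdout_per_condition: int = 5,
    n_repeats: int = 10,
    test_fraction: float = 0.2,
) -> list[SplitPlan]:
    """Build the train/test partitions for one validation scheme."""
    df = table.df.reset_index(drop=True)
    rng = np.random.default_rng(seed)
    labels = df["condition"].map(LABELS)
    if labels.isna().any():
        raise ValueError("unknown condition labels in feature table")
    if scheme == "split_8020":
        plans = []
        for r in range(n_repeats):
            train_idx, test_idx = train_test_split(
                np.arange(len(df)),
                test_size=test_fraction,
                stratify=labels,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            plans.append(
                SplitPlan("split_8020", r, np.sort(train_idx), np.sort(test_idx))
            )
        return plans
    if scheme == "l5o4t":
        participants = np.array(sorted(df["participant_id"].unique()))
        if participants.size < n_holdout_per_condition:
            raise ValueError(
                f"need >= {n_holdout_per_condition} participants, "
                f"got {participants.size}"
            )
        plans = []
        for r in range(n_repeats):
            held: dict[str, list[str]] = {}
            test_mask = np.zeros(len(df), dtype=bool)
            for condition in ("familiar", "unfamiliar"):
                chosen = rng.choice(
                    participants, size=n_holdout_per_condition, replace=False
                )
                held[condition] = sorted(map(str, chosen))
                test_mask |= (
                    df["participant_id"].isin(chosen)
                    & (df["condition"] == condition)
                ).to_numpy()
            plans.append(
                SplitPlan(
                    "l5o4t",
                    r,
                    np.flatnonzero(~test_mask),
                    np.flatnonzero(test_mask),
                    holdout_participants=held,
                )
            )
        return plans
    raise ValueError(f"unknown scheme {scheme!r}")


def assert_no_leakage(df: pd.DataFrame, plan: SplitPlan) -> None:
    """For L5O4T: no held-out (participant, condition) pair contributes any
    training row. Raised as AssertionError at fit time, not left to
    convention."""
    if plan.scheme != "l5o4t":
        return
    train = df.iloc[plan.train_ids]
    for condition, pids in plan.holdout_participants.items():
        bad = train[
            train["participant_id"].isin(pids) & (train["condition"] == condition)
        ]
        assert bad.empty, (
            f"leakage: held-out {condition} windows of {sorted(bad['participant_id'].unique())} in train"
        )


# ---------------------------------------------------------------------------
# tuning / training


def _grid_points(grid: dict[str, list]) -> list[dict]:
    keys = sorted(grid)
    return [dict(zip(keys, combo)) for combo in itertools.product(*(grid[k] for k in keys))]


def _make_clf(params: dict, seed: int) -> xgb.XGBClassifier:
    return xgb.XGBClassifier(
        objective="binary:logistic",
        eval_metric="logloss",
        random_state=seed,
        n_jobs=1,
        verbosity=0,
        **params,
    )


def tune_and_train(
    X: np.ndarray,
    y: np.ndarray,
    grid: dict[str, list] | None = None,
    *,
    seed: int = 0,
    n_cv_folds: int = 10,
    n_search_iter: int | None = 20,
    eval_set: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[xgb.XGBClassifier, ModelConfig]:
    """Search the hyperparameter grid by mean CV negative log-likelihood,
    then refit the winner on all training rows.

    The search is exhaustive when the grid has at most ``n_search_iter``
    points (or ``n_search_iter`` is None), randomized otherwise. With
    ``eval_set`` the final refit tracks per-round log-loss on both the
    training rows and the supplied held-out rows.
    """
    if grid is None:
        grid = DEFAULT_GRID
    points = _grid_points(grid)
    rng = np.random.default_rng(seed)
    if n_search_iter is not None and len(points) > n_search_iter:
        idx = rng.choice(len(points), size=n_search_iter, replace=False)
        points = [points[i] for i in sorted(idx)]
    n_folds = min(n_cv_folds, int(np.bincount(y).min()))
    if len(points) == 1:
        best = points[0]
    else:
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        folds = list(skf.split(X, y))
        best, best_score = None, np.inf
        for params in points:
            scores = []
            for tr, va in folds:
                assert np.intersect1d(tr, va).size == 0
                clf = _make_clf(params, seed)
                clf.fit(X[tr], y[tr])
                p = clf.predict_proba(X[va])[:, 1]
                scores.append(log_loss(y[va], p, labels=[0, 1]))
            score = float(np.mean(scores))
            if score < best_score:
                best, best_score = params, score
    clf = _make_clf(best, seed)
    if eval_set is not None:
        clf.fit(X, y, eval_set=[(X, y), eval_set], verbose=False)
    else:
        clf.fit(X, y)
    config = ModelConfig(**best, n_cv_folds=n_folds, seed=seed)
    return clf, config


def evaluate(
    model: xgb.XGBClassifier, X_test: np.ndarray, y_test: np.ndarray,
    config: ModelConfig | None = None,
) -> EvalReport:
    """Accuracy, confusion proportions and per-round log-loss curves."""
    pred = model.predict(X_test)
    accuracy = float(np.mean(pred == y_test))
    n = y_test.size
    confusion = {
        "familiar_as_familiar": float(np.sum((y_test == 1) & (pred == 1)) / n),
        "familiar_as_unfamiliar": float(np.sum((y_test == 1) & (pred == 0)) / n),
        "unfamiliar_as_familiar": float(np.sum((y_test == 0) & (pred == 1)) / n),
        "unfamiliar_as_unfamiliar": float(np.sum((y_test == 0) & (pred == 0)) / n),
    }
    evals = getattr(model, "evals_result_", None) or {}
    curves = list(evals.values())
    logloss_train = list(map(float, curves[0]["logloss"])) if curves else []
    logloss_test = list(map(float, curves[1]["logloss"])) if len(curves) > 1 else []
    return EvalReport(
        accuracy=accuracy,
        confusion=confusion,
        logloss_train=logloss_train,
        logloss_test=logloss_test,
        config=config or ModelConfig(),
        n_test=int(n),
    )


# ---------------------------------------------------------------------------
# SHAP importance


def feature_family_tag(name: str) -> str:
    """Coarse family of a feature column, for importance summaries."""
    if name.startswith("fix_"):
        return "fixation"
    if name.startswith(("sac_", "gl_")):
        return "saccade"
    if "yaw" in name:
        return "yaw"
    if name.startswith(("rel_roll", "rel_pitch")):
        return "orientation"
    if name.startswith("cep_"):
        return "cepstral"
    if name.startswith(("rel_acc", "p2p_", "acc_magn", "energy_", "mi_", "sma",
                        "mv", "entropy", "fundamental")):
        return "acceleration"
    if name.startswith(("zero_crossing", "spectral_", "chroma")):
        return "spectral"
    return "other"


def shap_values(model: xgb.XGBClassifier, X: np.ndarray) -> np.ndarray:
    """Per-row, per-feature TreeSHAP contributions (log-odds scale); the
    trailing bias column is dropped."""
    booster = model.get_booster()
    dm = xgb.DMatrix(np.asarray(X, dtype=np.float32))
    contribs = booster.predict(dm, pred_contribs=True)
    return contribs[:, :-1]


def shap_ranks(
    model: xgb.XGBClassifier,
    X: np.ndarray,
    feature_names: Sequence[str],
    k: int = 20,
) -> ImportanceReport:
    """Top-k features by mean absolute SHAP value, with family tags."""
    sv = shap_values(model, X)
    mean_abs = np.abs(sv).mean(axis=0)
    order = np.argsort(-mean_abs, kind="stable")[: min(k, len(feature_names))]
    ranking = [
        {
            "rank": r + 1,
            "feature": str(feature_names[i]),
            "family": feature_family_tag(str(feature_names[i])),
            "mean_abs_shap": float(mean_abs[i]),
        }
        for r, i in enumerate(order)
    ]
    return ImportanceReport(ranking=ranking)


# ---------------------------------------------------------------------------
# experiment driver


def _design_matrix(
    df: pd.DataFrame, columns: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    X = df[list(columns)].to_numpy(dtype=np.float32)
    y = df["condition"].map(LABELS).to_numpy(dtype=int)
    return X, y


def run_scheme(
    table: FeatureTable,
    feature_columns: Sequence[str],
    scheme: str,
    seed: int,
    *,
    grid: dict[str, list] | None = None,
    n_repeats: int = 10,
    n_holdout_per_condition: int = 5,
    n_cv_folds: int = 10,
    n_search_iter: int | None = 20,
    shap_k: int = 20,
) -> dict:
    """All repeats of one validation scheme on one feature set.

    Outlier statistics are fit on each repeat's training rows and applied to
    both partitions before fitting.
    """
    df = table.df.reset_index(drop=True)
    plans = make_split(
        table, scheme, seed,
        n_holdout_per_condition=n_holdout_per_condition, n_repeats=n_repeats,
    )
    repeats = []
    for plan in plans:
        assert_no_leakage(df, plan)
        train_df = df.iloc[plan.train_ids]
        test_df = df.iloc[plan.test_ids]
        means, sds = fit_outlier_stats(train_df, feature_columns)
        train_df = apply_outlier_filter(train_df, means, sds)
        test_df = apply_outlier_filter(test_df, means, sds)
        X_tr, y_tr = _design_matrix(train_df, feature_columns)
        X_te, y_te = _design_matrix(test_df, feature_columns)
        model, config = tune_and_train(
            X_tr, y_tr, grid,
            seed=seed + plan.repeat_index,
            n_cv_folds=n_cv_folds,
            n_search_iter=n_search_iter,
            eval_set=(X_te, y_te),
        )
        report = evaluate(model, X_te, y_te, config)
        importance = shap_ranks(model, X_te, feature_columns, k=shap_k)
        repeats.append(
            {
                "repeat": plan.repeat_index,
                "holdout_participants": plan.holdout_participants,
                "eval": report.to_dict(),
                "importance": importance.to_dict(),
            }
        )
    accs = [r["eval"]["accuracy"] for r in repeats]
    return {
        "scheme": scheme,
        "n_repeats": len(repeats),
        "accuracy_avg": float(np.mean(accs)),
        "accuracy_best": float(np.max(accs)),
        "accuracy_worst": float(np.min(accs)),
        "repeats": repeats,
    }


def run_experiment(
    table: FeatureTable,
    seed: int,
    feature_sets: Sequence[str] = ("gaze", "imu", "gaze+imu"),
    schemes: Sequence[str] = ("split_8020", "l5o4t"),
    **scheme_kwargs,
) -> dict:
    """The full feature-set × validation-scheme matrix as one JSON-ready
    report."""
    fam = table.families or {}
    gaze_cols = [c for c in table.feature_columns if fam.get(c) == "gaze"]
    imu_cols = [c for c in table.feature_columns if fam.get(c) == "imu"]
    sets = {"gaze": gaze_cols, "imu": imu_cols, "gaze+imu": gaze_cols + imu_cols}
    results = {}
    for fs in feature_sets:
        cols = sets[fs]
        if not cols:
            raise ValueError(f"feature set {fs!r} has no columns in the table")
        results[fs] = {
            scheme: run_scheme(table, cols, scheme, seed, **scheme_kwargs)
            for scheme in schemes
        }
    return {"seed": seed, "feature_sets": {k: len(v) for k, v in sets.items()},
            "results": results}


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1)
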