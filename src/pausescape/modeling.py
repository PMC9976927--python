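"""Gradient-boosted (and reference) regression models of the pausing index.

The central object is :class:`PausingRegressor`, a scikit-learn style
estimator (``fit`` / ``predict`` / ``get_params`` / ``set_params``, fitted
attributes with a trailing underscore) wrapping four learners:

- ``xgb``  — XGBoost gradient-boosted trees (the primary model),
- ``gbdt`` — LightGBM gradient-boosted trees,
- ``rf``   — random forest,
- ``ridge``— L2 linear regression (a linear reference expected to trail the
  tree learners, since binding features act non-additively).

Hyperparameters are selected by mean R^2 over a k-fold cross-validation on
the training split only; tree learners early-stop per fold on the held-out
fold. Model evaluation always happens on a holdout set drawn before any
training (no leakage: holdout ids never enter a CV fold).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import Ridge
from sklearn.metrics import r2_score
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_is_fitted

from .features import FeatureMatrix

LEARNERS = ("xgb", "gbdt", "rf", "ridge")


@dataclass
class ModelSpec:
    """Declarative training configuration mapped onto a PausingRegressor."""

    learner: str = "xgb"
    learning_rates: Tuple[float, ...] = (0.05, 0.1)
    max_depths: Tuple[int, ...] = (4, 6, 8)
    subsample: float = 0.8
    colsample: float = 0.8
    n_rounds: int = 2000
    early_stopping_rounds: int = 50
    ridge_alphas: Tuple[float, ...] = (0.1, 1.0, 10.0, 100.0)
    rf_n_estimators: int = 300
    rf_max_features: float = 0.5
    rf_min_samples_leaf: int = 5
    n_folds: int = 5
    holdout_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learner not in LEARNERS:
            raise ValueError(f"learner must be one of {LEARNERS}")
        if not (0.0 < self.holdout_fraction < 1.0):
            raise ValueError("holdout_fraction must be in (0, 1)")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")

    def make_estimator(self) -> "PausingRegressor":
        return PausingRegressor(
            learner=self.learner,
            learning_rates=self.learning_rates,
            max_depths=self.max_depths,
            subsample=self.subsample,
            colsample=self.colsample,
            n_rounds=self.n_rounds,
            early_stopping_rounds=self.early_stopping_rounds,
            ridge_alphas=self.ridge_alphas,
            rf_n_estimators=self.rf_n_estimators,
            rf_max_features=self.rf_max_features,
            rf_min_samples_leaf=self.rf_min_samples_leaf,
            n_folds=self.n_folds,
            seed=self.seed,
        )


@dataclass
class FitResult:
    """A fitted model with its CV table and holdout evaluation."""

    model: "PausingRegressor"
    cv_results: pd.DataFrame
    holdout_r2: float
    holdout_rho: float
    predictions: pd.Series  # indexed by holdout ids
    feature_list: List[str]


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    return pd.DataFrame(np.asarray(X, dtype=float))


class PausingRegressor(BaseEstimator, RegressorMixin):
    """Pausing-index regressor with internal CV hyperparameter selection.

    Parameters mirror :class:`ModelSpec`. After :meth:`fit`, the fitted
    attributes are ``model_`` (the underlying booster/estimator),
    ``best_params_``, ``cv_results_`` (one row per grid point with mean CV
    R^2), ``feature_names_in_`` and ``train_mean_`` (per-feature training
    means, used by the linear attribution route).
    """

    def __init__(
        self,
        learner: str = "xgb",
        learning_rates: Tuple[float, ...] = (0.05, 0.1),
        max_depths: Tuple[int, ...] = (4, 6, 8),
        subsample: float = 0.8,
        colsample: float = 0.8,
        n_rounds: int = 2000,
        early_stopping_rounds: int = 50,
        ridge_alphas: Tuple[float, ...] = (0.1, 1.0, 10.0, 100.0),
        rf_n_estimators: int = 300,
        rf_max_features: float = 0.5,
        rf_min_samples_leaf: int = 5,
        n_folds: int = 5,
        seed: int = 0,
    ):
        self.learner = learner
        self.learning_rates = learning_rates
        self.max_depths = max_depths
        self.subsample = subsample
        self.colsample = colsample
        self.n_rounds = n_rounds
        self.early_stopping_rounds = early_stopping_rounds
        self.ridge_alphas = ridge_alphas
        self.rf_n_estimators = rf_n_estimators
        self.rf_max_features = rf_max_features
        self.rf_min_samples_leaf = rf_min_samples_leaf
        self.n_folds = n_folds
        self.seed = seed

    # ------------------------------------------------------------------ fit
    def fit(self, X, y) -> "PausingRegressor":
        X = _as_frame(X)
        y = np.asarray(y, dtype=float)
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        if not np.all(np.isfinite(y)):
            raise ValueError("non-finite targets")
        if self.learner not in LEARNERS:
            raise ValueError(f"learner must be one of {LEARNERS}")
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        self.train_mean_ = X.mean(axis=0).to_numpy(dtype=float)

        if self.learner == "xgb":
            self._fit_xgb(X, y)
        elif self.learner == "gbdt":
            self._fit_gbdt(X, y)
        elif self.learner == "rf":
            self._fit_rf(X, y)
        else:
            self._fit_ridge(X, y)
        return self

    def _folds(self, n: int):
        kf = KFold(n_splits=self.n_folds, shuffle=True, random_state=self.seed)
        return list(kf.split(np.arange(n)))

    def _fit_xgb(self, X: pd.DataFrame, y: np.ndarray) -> None:
        import xgboost as xgb

        Xv = X.to_numpy(dtype=np.float32)
        rows = []
        for lr in self.learning_rates:
            for depth in self.max_depths:
                params = {
                    "objective": "reg:squarederror",
                    "eta": lr,
                    "max_depth": depth,
                    "subsample": self.subsample,
                    "colsample_bytree": self.colsample,
                    "seed": self.seed,
                    "nthread": 1,
                    "tree_method": "hist",
                }
                scores, iters = [], []
                for tr, va in self._folds(len(X)):
                    dtr = xgb.DMatrix(Xv[tr], label=y[tr])
                    dva = xgb.DMatrix(Xv[va], label=y[va])
                    bst = xgb.train(
                        params,
                        dtr,
                        num_boost_round=self.n_rounds,
                        evals=[(dva, "val")],
                        early_stopping_rounds=self.early_stopping_rounds,
                        verbose_eval=False,
                    )
                    best_it = getattr(bst, "best_iteration", self.n_rounds - 1)
                    pred = bst.predict(dva, iteration_range=(0, best_it + 1))
                    scores.append(r2_score(y[va], pred))
                    iters.append(best_it + 1)
                rows.append(
                    {
                        "learning_rate": lr,
                        "max_depth": depth,
                        "mean_cv_r2": float(np.mean(scores)),
                        "mean_rounds": float(np.mean(iters)),
                        "fold_r2": scores,
                    }
                )
        cv = pd.DataFrame(rows)
        # best mean CV R^2; ties -> fewer rounds, then smaller depth
        best = cv.sort_values(
            ["mean_cv_r2", "mean_rounds", "max_depth"],
            ascending=[False, True, True],
        ).iloc[0]
        self.cv_results_ = cv
        self.best_params_ = {
            "learning_rate": float(best["learning_rate"]),
            "max_depth": int(best["max_depth"]),
            "n_rounds": max(1, int(round(best["mean_rounds"]))),
        }
        params = {
            "objective": "reg:squarederror",
            "eta": self.best_params_["learning_rate"],
            "max_depth": self.best_params_["max_depth"],
            "subsample": self.subsample,
            "colsample_bytree": self.colsample,
            "seed": self.seed,
            "nthread": 1,
            "tree_method": "hist",
        }
        dall = xgb.DMatrix(Xv, label=y)
        self.model_ = xgb.train(
            params, dall, num_boost_round=self.best_params_["n_rounds"]
        )

    def _fit_gbdt(self, X: pd.DataFrame, y: np.ndarray) -> None:
        import lightgbm as lgb

        Xv = X.to_numpy(dtype=np.float32)
        rows = []
        for lr in self.learning_rates:
            for depth in self.max_depths:
                params = {
                    "objective": "regression",
                    "learning_rate": lr,
                    "max_depth": depth,
                    "num_leaves": min(2**depth, 256),
                    "bagging_fraction": self.subsample,
                    "bagging_freq": 1,
                    "feature_fraction": self.colsample,
                    "seed": self.seed,
                    "num_threads": 1,
                    "verbosity": -1,
                }
                scores, iters = [], []
                for tr, va in self._folds(len(X)):
                    dtr = lgb.Dataset(Xv[tr], label=y[tr])
                    dva = lgb.Dataset(Xv[va], label=y[va], reference=dtr)
                    bst = lgb.train(
                        params,
                        dtr,
                        num_boost_round=self.n_rounds,
                        valid_sets=[dva],
                        callbacks=[
                            lgb.early_stopping(self.early_stopping_rounds, verbose=False)
                        ],
                    )
                    pred = bst.predict(Xv[va], num_iteration=bst.best_iteration)
                    scores.append(r2_score(y[va], pred))
                    iters.append(bst.best_iteration)
                rows.append(
                    {
                        "learning_rate": lr,
                        "max_depth": depth,
                        "mean_cv_r2": float(np.mean(scores)),
                        "mean_rounds": float(np.mean(iters)),
                        "fold_r2": scores,
                    }
                )
        cv = pd.DataFrame(rows)
        best = cv.sort_values(
            ["mean_cv_r2", "mean_rounds", "max_depth"],
            ascending=[False, True, True],
        ).iloc[0]
        self.cv_results_ = cv
        self.best_params_ = {
            "learning_rate": float(best["learning_rate"]),
            "max_depth": int(best["max_depth"]),
            "n_rounds": max(1, int(round(best["mean_rounds"]))),
        }
        import lightgbm as lgb  # noqa: F811

        params = {
            "objective": "regression",
            "learning_rate": self.best_params_["learning_rate"],
            "max_depth": self.best_params_["max_depth"],
            "num_leaves": min(2 ** self.best_params_["max_depth"], 256),
            "bagging_fraction": self.subsample,
            "bagging_freq": 1,
            "feature_fraction": self.colsample,
            "seed": self.seed,
            "num_threads": 1,
            "verbosity": -1,
        }
        self.model_ = lgb.train(
            params,
            lgb.Dataset(Xv, label=y),
            num_boost_round=self.best_params_["n_rounds"],
        )

    def _fit_rf(self, X: pd.DataFrame, y: np.ndarray) -> None:
        Xv = X.to_numpy(dtype=np.float32)
        rows = []
        for depth in self.max_depths:
            scores = []
            for tr, va in self._folds(len(X)):
                rf = RandomForestRegressor(
                    n_estimators=self.rf_n_estimators,
                    max_depth=None if depth <= 0 else depth,
                    max_features=self.rf_max_features,
                    min_samples_leaf=self.rf_min_samples_leaf,
                    random_state=self.seed,
                    n_jobs=1,
                )
                rf.fit(Xv[tr], y[tr])
                scores.append(r2_score(y[va], rf.predict(Xv[va])))
            rows.append(
                {
                    "max_depth": depth,
                    "mean_cv_r2": float(np.mean(scores)),
                    "fold_r2": scores,
                }
            )
        cv = pd.DataFrame(rows)
        best = cv.sort_values(
            ["mean_cv_r2", "max_depth"], ascending=[False, True]
        ).iloc[0]
        self.cv_results_ = cv
        self.best_params_ = {"max_depth": int(best["max_depth"])}
        self.model_ = RandomForestRegressor(
            n_estimators=self.rf_n_estimators,
            max_depth=None
            if self.best_params_["max_depth"] <= 0
            else self.best_params_["max_depth"],
            max_features=self.rf_max_features,
            min_samples_leaf=self.rf_min_samples_leaf,
            random_state=self.seed,
            n_jobs=1,
        ).fit(Xv, y)
        self._rf_train_X_ = Xv  # kept for path attributions

    def _fit_ridge(self, X: pd.DataFrame, y: np.ndarray) -> None:
        Xv = X.to_numpy(dtype=float)
        rows = []
        for alpha in self.ridge_alphas:
            scores = []
            for tr, va in self._folds(len(X)):
                rr = Ridge(alpha=alpha).fit(Xv[tr], y[tr])
                scores.append(r2_score(y[va], rr.predict(Xv[va])))
            rows.append(
                {"alpha": alpha, "mean_cv_r2": float(np.mean(scores)), "fold_r2": scores}
            )
        cv = pd.DataFrame(rows)
        best = cv.sort_values(["mean_cv_r2", "alpha"], ascending=[False, True]).iloc[0]
        self.cv_results_ = cv
        self.best_params_ = {"alpha": float(best["alpha"])}
        self.model_ = Ridge(alpha=self.best_params_["alpha"]).fit(Xv, y)

    # -------------------------------------------------------------- predict
    def _check_columns(self, X: pd.DataFrame) -> pd.DataFrame:
        expected = list(self.feature_names_in_)
        got = list(X.columns)
        if got != expected:
            missing = [c for c in expected if c not in set(got)]
            extra = [c for c in got if c not in set(expected)]
            if missing or extra:
                raise ValueError(
                    f"feature columns mismatch: missing={missing[:5]} "
                    f"extra={extra[:5]} (showing up to 5 of each)"
                )
            X = X[expected]
        return X

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        X = _as_frame(X)
        if isinstance(X.columns[0] if len(X.columns) else None, str):
            X = self._check_columns(X)
        Xv = X.to_numpy(dtype=np.float32)
        if self.learner == "xgb":
            import xgboost as xgb

            return self.model_.predict(xgb.DMatrix(Xv))
        if self.learner == "gbdt":
            return self.model_.predict(Xv)
        return self.model_.predict(Xv)


# ----------------------------------------------------------------- wrappers


def split_holdout(
    ids: Sequence[str],
    targets: Optional[Mapping[str, float]] = None,
    fraction: float = 0.5,
    seed: int = 0,
) -> Tuple[List[str], List[str]]:
    """Random disjoint-and-exhaustive train/test split of transcript ids."""
    ids = list(ids)
    if len(ids) < 10:
        raise ValueError("need at least 10 ids to split")
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_test = int(round(len(ids) * fraction))
    test = sorted(ids[i] for i in perm[:n_test])
    train = sorted(ids[i] for i in perm[n_test:])
    return train, test


def train_model(X_train: pd.DataFrame, y_train, spec: ModelSpec) -> PausingRegressor:
    """Fit a PausingRegressor per the spec (CV selection + refit)."""
    return spec.make_estimator().fit(X_train, np.asarray(y_train, dtype=float))


def _safe_pearson(a, b) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(stats.pearsonr(a, b)[0])


def evaluate(model: PausingRegressor, X: pd.DataFrame, y) -> Tuple[float, float]:
    """Holdout metrics: (R^2, Pearson rho of observed vs predicted)."""
    y = np.asarray(y, dtype=float)
    pred = model.predict(X)
    return float(r2_score(y, pred)), _safe_pearson(y, pred)


def fit_and_evaluate(
    X: pd.DataFrame, y: Mapping[str, float] | pd.Series, spec: ModelSpec
) -> FitResult:
    """Holdout split -> CV-selected fit on the training half -> holdout eval."""
    y = pd.Series(y).loc[X.index].astype(float)
    train_ids, test_ids = split_holdout(
        list(X.index), fraction=spec.holdout_fraction, seed=spec.seed
    )
    assert not set(train_ids) & set(test_ids)
    model = train_model(X.loc[train_ids], y.loc[train_ids], spec)
    r2, rho = evaluate(model, X.loc[test_ids], y.loc[test_ids])
    preds = pd.Series(model.predict(X.loc[test_ids]), index=test_ids)
    return FitResult(
        model=model,
        cv_results=model.cv_results_,
        holdout_r2=r2,
        holdout_rho=rho,
        predictions=preds,
        feature_list=list(model.feature_names_in_),
    )


def synchronize_features(
    mA: FeatureMatrix, mB: FeatureMatrix
) -> Tuple[FeatureMatrix, FeatureMatrix]:
    """Restrict two matrices to their common columns, in identical order."""
    common = [c for c in mA.values.columns if c in set(mB.values.columns)]
    if not common:
        raise ValueError("no common feature columns between matrices")
    return mA.select_columns(common), mB.select_columns(common)


def differential_pausing_eval(
    yA: pd.Series,
    yB: pd.Series,
    predA_by_Bmodel: pd.Series,
    predB_by_Amodel: pd.Series,
    log2_fc_threshold: float = 1.0,
) -> Dict[str, float]:
    """Concordance of observed and predicted between-line PI differences.

    Transcripts shared by both cell lines are grouped into A-specific
    (yA - yB >= threshold), B-specific (<= -threshold) and stable; within
    each group the Pearson correlation of observed differences (yA - yB)
    with predicted differences (cross-model predictions) is reported.
    Groups with fewer than 3 members are omitted with a warning.
    """
    shared = yA.index.intersection(yB.index)
    shared = shared.intersection(predA_by_Bmodel.index).intersection(
        predB_by_Amodel.index
    )
    d_obs = yA.loc[shared] - yB.loc[shared]
    d_pred = predA_by_Bmodel.loc[shared] - predB_by_Amodel.loc[shared]
    groups = {
        "A_specific": d_obs >= log2_fc_threshold,
        "B_specific": d_obs <= -log2_fc_threshold,
        "stable": d_obs.abs() < log2_fc_threshold,
    }
    out: Dict[str, float] = {}
    for name, mask in groups.items():
        if mask.sum() < 3:
            warnings.warn(f"differential group {name!r} has < 3 members; omitted")
            continue
        out[name] = _safe_pearson(d_obs[mask], d_pred[mask])
    return out


def polii_only_model(
    polii_table: pd.DataFrame, y: Mapping[str, float] | pd.Series, spec: ModelSpec
) -> FitResult:
    """Reference model restricted to Pol II occupancy columns (no annotation)."""
    if polii_table.shape[1] == 0:
        raise ValueError("no Pol II (POLR2*) columns available")
    return fit_and_evaluate(polii_table, y, spec)
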