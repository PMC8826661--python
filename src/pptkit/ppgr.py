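"""Postprandial glucose response (PPGR) prediction.

Two interchangeable sklearn-style regressors predict a meal's 2-h iAUC:

* :class:`CarbCountingRegressor` — the clinical "carbohydrate counting"
  baseline, a univariate least-squares line on the meal's carbohydrate
  grams;
* :class:`PPGRBoostingRegressor` — a gradient-boosted ensemble of shallow
  regression trees over meal macronutrients plus per-person clinical and
  microbiome features. This is a trainable surrogate with the same
  interface as published clinical+microbiome PPGR predictors, not a
  reproduction of any published trained model.

Models are compared by leave-one-person-out (LOPO) cross-validation: each
participant's meals are predicted by a model trained on all other
participants, and pooled predicted-vs-measured explained variance is
reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.ensemble import GradientBoostingRegressor
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y


class CarbCountingRegressor(RegressorMixin, BaseEstimator):
    """Univariate least-squares fit of iAUC on carbohydrate grams.

    Parameters
    ----------
    carb_col : str
        Feature column holding carbohydrate grams when X is a DataFrame;
        with array input the first column is used.
    """

    def __init__(self, carb_col: str = "carb_g"):
        self.carb_col = carb_col

    def _carbs(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            if self.carb_col not in X.columns:
                raise ValueError(f"column {self.carb_col!r} not in X")
            return X[self.carb_col].to_numpy(dtype=float)
        X = check_array(X, ensure_2d=False)
        return X[:, 0] if X.ndim == 2 else X

    def fit(self, X, y):
        c = self._carbs(X)
        y = np.asarray(y, dtype=float)
        if len(c) != len(y):
            raise ValueError("X and y length mismatch")
        if len(c) < 2 or np.ptp(c) == 0:
            raise ValueError("need >= 2 meals with distinct carbohydrate content")
        self.slope_, self.intercept_ = np.polyfit(c, y, 1)
        self.n_features_in_ = 1 if np.ndim(X) == 1 else np.shape(X)[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "slope_")
        return self.intercept_ + self.slope_ * self._carbs(X)


class PPGRBoostingRegressor(RegressorMixin, BaseEstimator):
    """Gradient-boosted shallow-tree surrogate for clinical+microbiome
    PPGR prediction.

    Predictions are clipped at zero (an iAUC cannot be negative under the
    clipped convention) and are deterministic given ``random_state``.
    """

    def __init__(
        self,
        n_estimators: int = 200,
        max_depth: int = 3,
        learning_rate: float = 0.05,
        subsample: float = 1.0,
        min_train_meals: int = 50,
        random_state: int = 0,
    ):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.learning_rate = learning_rate
        self.subsample = subsample
        self.min_train_meals = min_train_meals
        self.random_state = random_state

    def fit(self, X, y):
        X_arr = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
        if not np.isfinite(X_arr).all():
            raise ValueError("features contain missing values; impute first")
        X_arr, y = check_X_y(X_arr, y)
        if len(y) < self.min_train_meals:
            raise ValueError(
                f"need >= {self.min_train_meals} training meals, got {len(y)}"
            )
        self.feature_names_in_ = (
            np.asarray(X.columns) if isinstance(X, pd.DataFrame) else None
        )
        self.model_ = GradientBoostingRegressor(
            n_estimators=self.n_estimators,
            max_depth=self.max_depth,
            learning_rate=self.learning_rate,
            subsample=self.subsample,
            random_state=self.random_state,
        ).fit(X_arr, y)
        self.n_features_in_ = X_arr.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        X_arr = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else check_array(X)
        return np.clip(self.model_.predict(X_arr), 0.0, None)


@dataclass
class PredictionEvaluation:
    """Pooled LOPO evaluation: per-meal table plus summary scores."""

    per_meal: pd.DataFrame  # columns: participant_id, predicted, measured
    explained_variance_pct: float
    correlation: float | None
    per_person: dict[str, float]  # per-person Pearson r (NaN-free subset)
    skipped_persons: list[str]

    def explained_variance(self, method: str = "pearson") -> float:
        """Explained variance (%), either squared pooled Pearson r
        (``"pearson"``) or 1 - SSE/SST (``"ss"``, can be negative)."""
        y = self.per_meal["measured"].to_numpy(float)
        p = self.per_meal["predicted"].to_numpy(float)
        if method == "pearson":
            return self.explained_variance_pct
        if method == "ss":
            sst = np.sum((y - y.mean()) ** 2)
            if sst == 0:
                return 0.0
            return float(100.0 * (1.0 - np.sum((y - p) ** 2) / sst))
        raise ValueError(f"unknown method {method!r}")


def pooled_explained_variance(measured, predicted) -> tuple[float, float | None]:
    """(explained variance %, Pearson r); r undefined (constant input) -> (0, None)."""
    y = np.asarray(measured, float)
    p = np.asarray(predicted, float)
    if len(y) < 2 or np.ptp(y) == 0 or np.ptp(p) == 0:
        return 0.0, None
    r = float(stats.pearsonr(p, y).statistic)
    return 100.0 * r * r, r


def lopo_evaluate(
    data: pd.DataFrame,
    estimator,
    feature_cols: list[str],
    target_col: str = "iauc",
    person_col: str = "participant_id",
) -> PredictionEvaluation:
    """Leave-one-person-out cross-validation of a PPGR predictor.

    For each participant the estimator is cloned, fitted on every other
    participant's meals and used to predict the held-out participant's
    meals; a participant's own meals never enter their training fold.
    Explained variance is 100 x (squared pooled Pearson correlation) of
    predicted vs measured across all held-out meals; a constant prediction
    vector yields 0.
    """
    persons = data[person_col].unique()
    if len(persons) < 2:
        raise ValueError("leave-one-person-out needs >= 2 persons")
    rows = []
    skipped = []
    for pid in persons:
        test = data[data[person_col] == pid]
        train = data[data[person_col] != pid]
        if len(test) == 0:
            skipped.append(pid)
            continue
        assert not (train[person_col] == pid).any()
        est = clone(estimator)
        est.fit(train[feature_cols], train[target_col].to_numpy(float))
        pred = np.asarray(est.predict(test[feature_cols]), float)
        rows.append(
            pd.DataFrame(
                {
                    person_col: pid,
                    "predicted": pred,
                    "measured": test[target_col].to_numpy(float),
                }
            )
        )
    per_meal = pd.concat(rows, ignore_index=True)
    ev, r = pooled_explained_variance(per_meal["measured"], per_meal["predicted"])
    per_person = {}
    for pid, grp in per_meal.groupby(person_col):
        _, rp = pooled_explained_variance(grp["measured"], grp["predicted"])
        if rp is not None:
            per_person[pid] = rp
    return PredictionEvaluation(
        per_meal=per_meal,
        explained_variance_pct=ev,
        correlation=r,
        per_person=per_person,
        skipped_persons=skipped,
    )
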