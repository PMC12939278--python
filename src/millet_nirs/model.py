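"""Calibration models and their evaluation protocol.

Three model families are fitted on the selected key wavelengths:

* PLS — latent-variable count chosen by seeded 5-fold cross-validation;
* random forest — 100 trees, minimum leaf size 5, depth limited only by
  the leaf-size rule;
* SVR — RBF kernel, with cost, kernel width and epsilon tuned by seeded
  random search scored by 5-fold CV error.

Predictors are standardised (training-set mean/SD) before PLS and SVR;
the forest sees raw values. Every model is scored on both partitions by
R-squared, RMSE (population denominator n) and RPD, the ratio of the
evaluated set's reference SD (n-1) to its RMSE; RPD > 2.0 reads as good
to excellent predictive power, 1.4-2.0 as moderate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

__all__ = [
    "ModelSpec",
    "TrainedModel",
    "MetricsReport",
    "fit",
    "evaluate",
    "evaluate_model",
    "compare",
]

FAMILIES = ("PLS", "RF", "SVM")


@dataclass(frozen=True)
class ModelSpec:
    """Which family to fit and with what hyperparameter policy."""

    family: str
    seed: int = 0
    # PLS: upper bound on the CV-selected latent-variable count
    max_components: int = 20
    # RF
    n_trees: int = 100
    min_leaf: int = 5
    # SVR random search
    n_search: int = 60
    cv_folds: int = 5

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")


@dataclass
class TrainedModel:
    """A fitted estimator plus the choices made while fitting it."""

    spec: ModelSpec
    estimator: object
    chosen: dict = field(default_factory=dict)

    def predict(self, X) -> np.ndarray:
        return np.asarray(self.estimator.predict(np.asarray(X, dtype=float))).ravel()


@dataclass(frozen=True)
class MetricsReport:
    """Training (calibration) and prediction metrics of one model."""

    family: str
    r2_c: float
    rmse_c: float
    rpd_c: float
    r2_p: float
    rmse_p: float
    rpd_p: float

    def as_dict(self) -> dict:
        return {
            "Model": self.family,
            "R2_C": self.r2_c,
            "RMSE_C": self.rmse_c,
            "RPD_C": self.rpd_c,
            "R2_P": self.r2_p,
            "RMSE_P": self.rmse_p,
            "RPD_P": self.rpd_p,
        }


def _cv_mse(estimator_factory, X, y, folds) -> float:
    mse = 0.0
    for train, test in folds:
        est = estimator_factory()
        est.fit(X[train], y[train])
        pred = np.asarray(est.predict(X[test])).ravel()
        mse += float(np.mean((y[test] - pred) ** 2))
    return mse / len(folds)


def _kfold(n: int, k: int, seed: int):
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    return list(kf.split(np.arange(n)))


def fit(spec: ModelSpec, X_train, y_train) -> TrainedModel:
    """Fit one calibration model with its family's tuning protocol."""
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(y_train, dtype=float).ravel()
    if X.shape[0] < 10:
        raise ValueError("need at least 10 training samples")
    if np.std(y) == 0 and spec.family != "RF":
        # CV-based hyperparameter selection is meaningless on a flat response;
        # the forest needs no tuning and just predicts the constant
        raise ValueError("degenerate response: zero variance")
    folds = _kfold(X.shape[0], spec.cv_folds, spec.seed)

    if spec.family == "PLS":
        min_fold_train = min(len(tr) for tr, _ in folds)
        max_a = min(spec.max_components, X.shape[1], min_fold_train - 1)
        best_a, best_mse = 1, math.inf
        for a in range(1, max_a + 1):
            mse = _cv_mse(
                lambda a=a: Pipeline(
                    [("scale", StandardScaler()), ("pls", PLSRegression(n_components=a))]
                ),
                X,
                y,
                folds,
            )
            if mse < best_mse:
                best_a, best_mse = a, mse
        est = Pipeline(
            [("scale", StandardScaler()), ("pls", PLSRegression(n_components=best_a))]
        )
        est.fit(X, y)
        return TrainedModel(spec, est, {"n_components": best_a, "cv_mse": best_mse})

    if spec.family == "RF":
        est = RandomForestRegressor(
            n_estimators=spec.n_trees,
            min_samples_leaf=spec.min_leaf,
            random_state=spec.seed,
        )
        est.fit(X, y)
        return TrainedModel(spec, est, {"n_trees": spec.n_trees, "min_leaf": spec.min_leaf})

    # SVR: random search over cost 10^[-1,3], width 10^[-4,1], eps [0.01, 0.3]
    rng = np.random.default_rng(spec.seed)
    draws = [
        {
            "C": 10.0 ** rng.uniform(-1, 3),
            "gamma": 10.0 ** rng.uniform(-4, 1),
            "epsilon": rng.uniform(0.01, 0.3),
        }
        for _ in range(spec.n_search)
    ]
    best_params, best_mse = None, math.inf
    for params in draws:
        mse = _cv_mse(
            lambda p=params: Pipeline(
                [("scale", StandardScaler()), ("svr", SVR(kernel="rbf", **p))]
            ),
            X,
            y,
            folds,
        )
        if mse < best_mse:
            best_params, best_mse = params, mse
    est = Pipeline([("scale", StandardScaler()), ("svr", SVR(kernel="rbf", **best_params))])
    est.fit(X, y)
    return TrainedModel(spec, est, {**best_params, "cv_mse": best_mse})


def evaluate(y_true, y_pred) -> tuple[float, float, float]:
    """(R2, RMSE, RPD) of predictions on one partition.

    R2 = 1 - SSE/SST; RMSE uses the population denominator n; RPD is the
    evaluated set's reference SD (n-1 denominator) over its RMSE, with a
    +inf sentinel for a perfect fit.
    """
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    n = y_true.size
    if n < 2:
        raise ValueError("evaluation needs at least 2 samples")
    sse = float(np.sum((y_true - y_pred) ** 2))
    sst = float(np.sum((y_true - y_true.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else (1.0 if sse == 0 else -math.inf)
    rmse = math.sqrt(sse / n)
    sd = float(np.std(y_true, ddof=1))
    rpd = sd / rmse if rmse > 0 else math.inf
    return r2, rmse, rpd


def evaluate_model(model: TrainedModel, X_train, y_train, X_test, y_test) -> MetricsReport:
    """Score a fitted model on both partitions."""
    r2_c, rmse_c, rpd_c = evaluate(y_train, model.predict(X_train))
    r2_p, rmse_p, rpd_p = evaluate(y_test, model.predict(X_test))
    return MetricsReport(
        family=model.spec.family,
        r2_c=r2_c,
        rmse_c=rmse_c,
        rpd_c=rpd_c,
        r2_p=r2_p,
        rmse_p=rmse_p,
        rpd_p=rpd_p,
    )


def compare(reports: list[MetricsReport]) -> list[MetricsReport]:
    """Rank model families by prediction-set R2 (ties: lower prediction RMSE)."""
    if not reports:
        raise ValueError("no reports to compare")
    return sorted(reports, key=lambda r: (-r.r2_p, r.rmse_p))
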