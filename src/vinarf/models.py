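"""Regression models over the descriptor tables.

Three trainable model families are supported, mirroring the usual scoring-
function taxonomy:

* ``mlr`` — ordinary least squares on the six Vina features (a classical,
  additive scoring function recalibrated to a training set);
* ``rf`` — random-forest regression (bootstrap CART ensemble) on either the
  6-feature or 42-feature scheme.  For each random seed, the forest's
  ``mtry`` (features tried per split) is selected by the lowest RMSE of the
  out-of-bag (OOB) predictions over a candidate grid, ties going to the
  smallest mtry.  Ten seeds give ten model instances whose test metrics are
  summarised by their componentwise median.
* the untrained Vina composite score lives in :mod:`vinarf.interactions`.

The forest learner is scikit-learn's RandomForestRegressor; everything the
contract needs (bootstrap resampling, per-split feature subsampling, OOB
predictions, full determinism given a seed) is exposed through it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .config import DEFAULT_SEEDS
from .metrics import MetricsReport, PredictionSet, compute_metrics, median_summary

logger = logging.getLogger(__name__)

__all__ = [
    "LinearModel",
    "RFConfig",
    "TrainedModel",
    "EnsembleResult",
    "FeatureMismatchError",
    "fit_mlr",
    "select_mtry",
    "fit_rf",
    "fit_rf_ensemble",
    "predict",
]


class FeatureMismatchError(ValueError):
    """Prediction-time columns do not match the model's training columns."""

    def __init__(self, missing: list[str], extra: list[str]):
        self.missing, self.extra = missing, extra
        super().__init__(f"feature mismatch: missing={missing}, extra={extra}")


@dataclass
class LinearModel:
    intercept: float
    coefficients: np.ndarray
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.coefficients) != len(self.feature_names):
            raise ValueError("coefficient length must equal feature count")


@dataclass
class RFConfig:
    """Forest ensemble settings: 500 trees, a full mtry grid, 10 seeds."""

    n_trees: int = 500
    mtry_grid: tuple[int, ...] | None = None  # default: 1..n_features
    seeds: tuple[int, ...] = DEFAULT_SEEDS

    def grid_for(self, n_features: int) -> tuple[int, ...]:
        grid = self.mtry_grid if self.mtry_grid is not None else tuple(range(1, n_features + 1))
        if not grid:
            raise ValueError("mtry grid is empty")
        bad = [m for m in grid if not 1 <= m <= n_features]
        if bad:
            raise ValueError(f"mtry values out of [1, {n_features}]: {bad}")
        return tuple(grid)


@dataclass
class TrainedModel:
    """A fitted predictor plus the provenance the ensemble bookkeeping needs."""

    kind: str  # "mlr" | "rf"
    feature_names: tuple[str, ...]
    predictor: object
    seed: int | None = None
    selected_mtry: int | None = None
    oob_rmse_by_mtry: dict[int, float] | None = None


@dataclass
class EnsembleResult:
    models: list[TrainedModel]
    per_seed_reports: list[MetricsReport] = field(default_factory=list)

    @property
    def median_report(self) -> MetricsReport:
        return median_summary(self.per_seed_reports)


def _as_matrix(X: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), tuple(X.columns)
    arr = np.asarray(X, dtype=float)
    return arr, tuple(f"x{i}" for i in range(arr.shape[1]))


def fit_mlr(X: pd.DataFrame | np.ndarray, y: np.ndarray) -> LinearModel:
    """Ordinary least squares fit of y on X (with intercept); deterministic.

    Rank-deficient designs are solved in the minimum-norm sense with a logged
    warning; n <= p is an error.
    """
    Xm, names = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    n, p = Xm.shape
    if len(y) != n:
        raise ValueError("X and y disagree on sample count")
    if n <= p:
        raise ValueError(f"need more samples ({n}) than features ({p}) for OLS")
    design = np.column_stack([np.ones(n), Xm])
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < p + 1:
        logger.warning(
            "rank-deficient design (rank %d < %d); minimum-norm pseudo-inverse fit",
            rank, p + 1,
        )
    return LinearModel(intercept=float(coef[0]), coefficients=coef[1:], feature_names=names)


def _make_forest(n_trees: int, mtry: int, seed: int, oob: bool) -> RandomForestRegressor:
    return RandomForestRegressor(
        n_estimators=n_trees,
        max_features=mtry,
        bootstrap=True,
        oob_score=oob,
        random_state=seed,
        n_jobs=1,
    )


def select_mtry(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    seed: int,
    config: RFConfig,
) -> tuple[int, dict[int, float], dict[int, RandomForestRegressor]]:
    """OOB-driven mtry selection: one forest per grid value, same seed.

    Returns (selected mtry, OOB-RMSE curve, fitted forests keyed by mtry) so
    the winning forest can be reused without refitting.  Samples that never
    fall out of bag are excluded from the OOB RMSE with a warning.
    """
    Xm, _ = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    grid = config.grid_for(Xm.shape[1])
    curve: dict[int, float] = {}
    forests: dict[int, RandomForestRegressor] = {}
    import warnings

    for mtry in grid:
        forest = _make_forest(config.n_trees, mtry, seed, oob=True)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            forest.fit(Xm, y)
        oob_pred = np.asarray(forest.oob_prediction_, dtype=float)
        valid = np.isfinite(oob_pred)
        # sklearn reports never-OOB samples (tiny n) with a warning and a 0.0
        # placeholder prediction; exclude those from the OOB RMSE.
        if any("out-of-bag" in str(w.message).lower() for w in caught):
            valid &= oob_pred != 0.0
            logger.warning(
                "%d samples had no out-of-bag trees at mtry=%d; excluded from OOB RMSE",
                int((~valid).sum()), mtry,
            )
        curve[mtry] = float(np.sqrt(np.mean((y[valid] - oob_pred[valid]) ** 2)))
        forests[mtry] = forest
    # argmin with ties to the smallest mtry (grid iterated ascending)
    best = min(sorted(curve), key=lambda m: (curve[m], m))
    return best, curve, forests


def fit_rf(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    seed: int,
    config: RFConfig | None = None,
) -> TrainedModel:
    """One RF model instance: OOB mtry selection, then the forest at that mtry."""
    config = config or RFConfig()
    _, names = _as_matrix(X)
    mtry, curve, forests = select_mtry(X, y, seed, config)
    return TrainedModel(
        kind="rf",
        feature_names=names,
        predictor=forests[mtry],
        seed=seed,
        selected_mtry=mtry,
        oob_rmse_by_mtry=curve,
    )


def fit_rf_ensemble(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    config: RFConfig | None = None,
) -> EnsembleResult:
    """One RF model instance per seed (10 by default)."""
    config = config or RFConfig()
    models = [fit_rf(X, y, seed, config) for seed in config.seeds]
    return EnsembleResult(models=models)


def predict(model: TrainedModel | LinearModel, X: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Predictions p(n) = f(x(n)); columns are checked against training names."""
    if isinstance(model, LinearModel):
        Xm = _align(X, model.feature_names)
        return model.intercept + Xm @ model.coefficients
    if model.kind == "mlr":
        return predict(model.predictor, X)
    Xm = _align(X, model.feature_names)
    return np.asarray(model.predictor.predict(Xm), dtype=float)


def _align(X: pd.DataFrame | np.ndarray, names: tuple[str, ...]) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        missing = [c for c in names if c not in X.columns]
        extra = [c for c in X.columns if c not in names]
        if missing or extra:
            raise FeatureMismatchError(missing, extra)
        return X.loc[:, list(names)].to_numpy(dtype=float)
    arr = np.asarray(X, dtype=float)
    if arr.shape[1] != len(names):
        raise FeatureMismatchError(list(names[arr.shape[1]:]), [])
    return arr


def evaluate_ensemble(
    ens: EnsembleResult,
    X_test: pd.DataFrame | np.ndarray,
    y_test: np.ndarray,
    sd_ddof: int = 1,
) -> EnsembleResult:
    """Fill per-seed test metrics for an ensemble; returns the same object."""
    y_test = np.asarray(y_test, dtype=float)
    ens.per_seed_reports = [
        compute_metrics(PredictionSet(predict(m, X_test), y_test), sd_ddof=sd_ddof)
        for m in ens.models
    ]
    return ens
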