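"""Leave-one-subject-out (LOSO) cross-subject evaluation.

For each target muscle, a regressor predicts that muscle's peak-normalized
RMS from the other five muscles' normalized RMS plus the encoded movement.
Each fold holds out all windows of one subject, so every score measures
generalization to an unseen person. The model menu is support-vector
regression, k-nearest neighbours, AdaBoost and gradient-boosted trees
(XGBoost); boosting internals are delegated to their established
implementations. Models are ranked by R² first (how much activation
variance they explain across subjects), MSE second.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostRegressor
from sklearn.neighbors import KNeighborsRegressor
from sklearn.svm import SVR
from xgboost import XGBRegressor

from .cohort import LAYER_MAP, MUSCLES

__all__ = [
    "MODEL_KINDS",
    "ModelSpec",
    "CVFoldResult",
    "CVReport",
    "build_estimator",
    "mse",
    "r_squared",
    "pearson_r_from_r2",
    "loso_folds",
    "fit_predict_target",
    "run_comparison",
    "per_muscle_summary",
]

MODEL_KINDS = ("svr", "knn", "adaboost", "xgboost")

_KIND_ALIASES = {
    "svr": "svr",
    "support-vector regressor": "svr",
    "knn": "knn",
    "k-nearest-neighbour regressor": "knn",
    "adaboost": "adaboost",
    "adaptive-boosting regressor": "adaboost",
    "xgboost": "xgboost",
    "xgb": "xgboost",
    "gradient-boosted-tree regressor": "xgboost",
}


@dataclass(frozen=True)
class ModelSpec:
    """A model kind plus hyperparameter overrides and a seed.

    No tuning is performed: the established implementations' defaults are
    used (and recorded in reports) unless ``params`` overrides them. The
    seed is applied to stochastic learners only.
    """

    kind: str
    params: Mapping[str, object] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        canon = _KIND_ALIASES.get(self.kind.lower())
        if canon is None:
            raise ValueError(f"unknown model kind {self.kind!r}; valid: {MODEL_KINDS}")
        object.__setattr__(self, "kind", canon)


def build_estimator(spec: ModelSpec):
    """Instantiate the scikit-learn / xgboost estimator for a spec."""
    params = dict(spec.params)
    if spec.kind == "svr":
        return SVR(**params)
    if spec.kind == "knn":
        return KNeighborsRegressor(**params)
    if spec.kind == "adaboost":
        params.setdefault("random_state", spec.seed)
        return AdaBoostRegressor(**params)
    if spec.kind == "xgboost":
        params.setdefault("random_state", spec.seed)
        params.setdefault("n_jobs", 1)
        return XGBRegressor(**params)
    raise ValueError(f"unknown model kind {spec.kind!r}")  # pragma: no cover


def mse(y: Sequence[float], y_pred: Sequence[float]) -> float:
    """Mean squared error, (1/n)·Σ(yᵢ − ŷᵢ)²."""
    y = np.asarray(y, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {y_pred.shape}")
    if y.size == 0:
        raise ValueError("empty input")
    return float(np.mean((y - y_pred) ** 2))


def r_squared(y: Sequence[float], y_pred: Sequence[float]) -> float:
    """Coefficient of determination, 1 − SSres/SStot about the mean of y.

    Negative values mean the model predicts worse than the observed mean.
    A constant ``y`` leaves the denominator zero and raises.
    """
    y = np.asarray(y, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {y_pred.shape}")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("R² undefined for constant y (zero total sum of squares)")
    ss_res = float(np.sum((y - y_pred) ** 2))
    return 1.0 - ss_res / ss_tot


def pearson_r_from_r2(r2: float) -> float:
    """Pearson correlation magnitude implied by an R² value, √R²."""
    if r2 < 0:
        raise ValueError("R² must be nonnegative to imply a correlation")
    return float(np.sqrt(r2))


def loso_folds(table: pd.DataFrame) -> list[tuple[np.ndarray, np.ndarray]]:
    """One (train_index, test_index) pair per subject.

    The test fold holds all and only that subject's rows; folds partition
    the table. At least two subjects are required.
    """
    subjects = sorted(table["subject_id"].unique())
    if len(subjects) < 2:
        raise ValueError(
            f"leave-one-subject-out needs >= 2 subjects, got {len(subjects)}"
        )
    folds = []
    for subject in subjects:
        test_mask = (table["subject_id"] == subject).to_numpy()
        folds.append((table.index[~test_mask].to_numpy(), table.index[test_mask].to_numpy()))
    return folds


def _design(
    rows: pd.DataFrame,
    target_muscle: str,
    muscles: Sequence[str],
    include_movement: bool,
    one_hot_movement: bool,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    feature_muscles = [m for m in muscles if m != target_muscle]
    columns = list(feature_muscles)
    X = rows[feature_muscles].to_numpy(dtype=float)
    if include_movement:
        if one_hot_movement:
            codes = rows["movement_code"].to_numpy()
            onehot = np.stack([(codes == c).astype(float) for c in range(4)], axis=1)
            X = np.hstack([X, onehot])
            columns += [f"movement=={c}" for c in range(4)]
        else:
            X = np.hstack([X, rows[["movement_code"]].to_numpy(dtype=float)])
            columns.append("movement_code")
    y = rows[target_muscle].to_numpy(dtype=float)
    return X, y, columns


def fit_predict_target(
    train_rows: pd.DataFrame,
    test_rows: pd.DataFrame,
    target_muscle: str,
    spec: ModelSpec,
    muscles: Sequence[str] = MUSCLES,
    include_movement: bool = True,
    one_hot_movement: bool = False,
) -> tuple[np.ndarray, float]:
    """Fit one model for one target muscle and predict the test rows.

    Features are the five non-target muscles' normalized RMS plus the
    movement code; the target muscle never appears among the features.
    Returns (predictions in test-row order, training wall time in seconds
    measured around the fit call only).
    """
    if target_muscle not in muscles or target_muscle not in train_rows.columns:
        raise ValueError(f"target muscle {target_muscle!r} absent from the table")
    if len(train_rows) == 0:
        raise ValueError("empty training set")
    X_train, y_train, feat_names = _design(
        train_rows, target_muscle, muscles, include_movement, one_hot_movement
    )
    X_test, _, _ = _design(
        test_rows, target_muscle, muscles, include_movement, one_hot_movement
    )
    assert target_muscle not in feat_names
    est = build_estimator(spec)
    t0 = time.perf_counter()
    est.fit(X_train, y_train)
    train_time = time.perf_counter() - t0
    return np.asarray(est.predict(X_test), dtype=float), train_time


@dataclass(frozen=True)
class CVFoldResult:
    """Scores for one (model, held-out subject, target muscle) cell."""

    model: str
    held_out_subject: str
    target_muscle: str
    mse: float
    r2: float
    train_time: float
    n_test_windows: int

    def __post_init__(self) -> None:
        if self.mse < 0:
            raise ValueError("mse must be nonnegative")
        if self.r2 > 1.0 + 1e-12:
            raise ValueError("r2 cannot exceed 1")
        if self.n_test_windows <= 0:
            raise ValueError("n_test_windows must be positive")


@dataclass
class CVReport:
    """All fold results of a model comparison, with aggregation helpers.

    ``predictions[kind]`` holds the pooled LOSO test-set predictions, one
    column per target muscle, indexed like the feature table — each row
    was predicted by the model that never saw that subject.
    """

    folds: list[CVFoldResult]
    predictions: dict[str, pd.DataFrame] = field(default_factory=dict)
    hyperparameters: dict[str, dict] = field(default_factory=dict)
    layer_map: dict[str, str] = field(default_factory=lambda: dict(LAYER_MAP))
    aggregate: str = "unweighted"

    def fold_table(self) -> pd.DataFrame:
        return pd.DataFrame([vars(f) for f in self.folds])

    def _cell_means(self, frame: pd.DataFrame, by: list[str]) -> pd.DataFrame:
        if self.aggregate == "unweighted":
            return frame.groupby(by, sort=True).agg(
                mse=("mse", "mean"),
                r2=("r2", "mean"),
                mse_sd=("mse", "std"),
                r2_sd=("r2", "std"),
                train_time=("train_time", "sum"),
            )
        if self.aggregate == "windows":
            def _agg(g: pd.DataFrame) -> pd.Series:
                w = g["n_test_windows"]
                return pd.Series(
                    {
                        "mse": np.average(g["mse"], weights=w),
                        "r2": np.average(g["r2"], weights=w),
                        "mse_sd": g["mse"].std(),
                        "r2_sd": g["r2"].std(),
                        "train_time": g["train_time"].sum(),
                    }
                )
            return frame.groupby(by, sort=True).apply(_agg, include_groups=False)
        raise ValueError(f"unknown aggregation rule {self.aggregate!r}")

    def per_model_summary(self) -> pd.DataFrame:
        """Grand mean MSE/R² per model over fold × muscle cells, with the
        fold-wise dispersion and total training time — the comparison table."""
        summary = self._cell_means(self.fold_table(), ["model"])
        return summary.sort_values(["r2", "mse"], ascending=[False, True])

    def per_muscle_summary(self, model: str) -> pd.DataFrame:
        """Mean MSE/R² per target muscle across folds for one model,
        tagged by anatomical layer (superficial/deep)."""
        frame = self.fold_table()
        frame = frame[frame["model"] == model]
        if frame.empty:
            raise ValueError(f"no fold results for model {model!r}")
        out = self._cell_means(frame, ["target_muscle"]).reset_index()
        out["layer"] = out["target_muscle"].map(self.layer_map)
        return out.sort_values(["layer", "target_muscle"], ascending=[False, True]).reset_index(
            drop=True
        )

    def ranking(self) -> list[str]:
        """Model kinds best-first: primary key R² (descending), secondary MSE."""
        return list(self.per_model_summary().index)

    def grand(self, model: str, metric: str) -> float:
        return float(self.per_model_summary().loc[model, metric])


def run_comparison(
    table: pd.DataFrame,
    specs: Sequence[ModelSpec],
    muscles: Sequence[str] | None = None,
    include_movement: bool = True,
    one_hot_movement: bool = False,
    aggregate: str = "unweighted",
) -> CVReport:
    """Evaluate every model spec on every LOSO fold and target muscle.

    Produces one :class:`CVFoldResult` per (spec, fold, muscle) plus pooled
    out-of-fold predictions per model, which downstream dosing uses as the
    predicted activation field.
    """
    if not specs:
        raise ValueError("no model specs supplied")
    muscles = tuple(muscles or table.attrs.get("muscles", MUSCLES))
    layer_map = dict(table.attrs.get("layer_map", LAYER_MAP))
    folds = loso_folds(table)
    results: list[CVFoldResult] = []
    predictions: dict[str, pd.DataFrame] = {}
    hyper: dict[str, dict] = {}
    for spec in specs:
        hyper[spec.kind] = {
            k: v for k, v in build_estimator(spec).get_params().items() if _jsonable(v)
        }
        pred_frame = pd.DataFrame(
            index=table.index, columns=list(muscles), dtype=float
        )
        for train_idx, test_idx in folds:
            train_rows = table.loc[train_idx]
            test_rows = table.loc[test_idx]
            subject = str(test_rows["subject_id"].iloc[0])
            for target in muscles:
                y_pred, t_fit = fit_predict_target(
                    train_rows,
                    test_rows,
                    target,
                    spec,
                    muscles=muscles,
                    include_movement=include_movement,
                    one_hot_movement=one_hot_movement,
                )
                y_true = test_rows[target].to_numpy(dtype=float)
                results.append(
                    CVFoldResult(
                        model=spec.kind,
                        held_out_subject=subject,
                        target_muscle=target,
                        mse=mse(y_true, y_pred),
                        r2=r_squared(y_true, y_pred),
                        train_time=t_fit,
                        n_test_windows=len(test_idx),
                    )
                )
                pred_frame.loc[test_idx, target] = y_pred
        predictions[spec.kind] = pred_frame
    return CVReport(
        folds=results,
        predictions=predictions,
        hyperparameters=hyper,
        layer_map=layer_map,
        aggregate=aggregate,
    )


def per_muscle_summary(report: CVReport, model: str = "xgboost") -> pd.DataFrame:
    """Module-level convenience wrapper for :meth:`CVReport.per_muscle_summary`."""
    return report.per_muscle_summary(model)


def _jsonable(v) -> bool:
    return isinstance(v, (bool, int, float, str, type(None), list, tuple))
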