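"""Multi-output surrogate regressors mapping 9 process inputs to 4 KPIs.

Four model families are compared on equal footing: ordinary least
squares, partial-least-squares projection, a (small) random forest, and a
feedforward neural network (multilayer perceptron).  Each trained
surrogate travels with the input/output standardization fit on its
training data, so callers always see physical units, and with provenance
(seed, data hash, final regularized loss and training R²).

Predictions outside the training range of any input are allowed -- the
screening stage relies on mild extrapolation -- but are flagged per row.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.neural_network import MLPRegressor

from .datastore import INPUT_FEATURES, OUTPUT_KPIS
from .metrics import PenaltySpec, PredictionPair, loss_mse_l2, r2_score
from .preprocess import ScalerModel, apply_scaler, fit_scaler, inverse_scaler

__all__ = [
    "FAMILIES",
    "ModelSpec",
    "TrainedSurrogate",
    "ComparisonResult",
    "fit_surrogate",
    "predict_kpis",
    "compare_models",
    "tune_hyperparameters",
    "default_specs",
]

FAMILIES = ("linear", "latent_projection", "tree_ensemble", "feedforward_net")


@dataclass(frozen=True)
class ModelSpec:
    """Family plus the hyperparameters that matter for it."""

    family: str = "feedforward_net"
    hidden_layers: tuple = (100, 50, 25, 50, 100)
    activation: str = "tanh"  # tuned on the simulated dataset; relu available
    solver: str = "adam"
    alpha: float = 0.1  # L2 weight
    learning_rate_init: float = 3e-3  # tuned
    n_iter_no_change: int = 30
    n_components: int = 4  # latent_projection
    n_trees: int = 4  # tree_ensemble
    max_iter: int = 2000
    tol: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if any(h <= 0 for h in self.hidden_layers):
            raise ValueError("hidden layer sizes must be positive")
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")

    @property
    def parameter_count(self) -> int:
        """Rough free-parameter count, used only for tie-breaking."""
        if self.family == "feedforward_net":
            sizes = (9, *self.hidden_layers, 4)
            return int(sum((a + 1) * b for a, b in zip(sizes[:-1], sizes[1:])))
        if self.family == "tree_ensemble":
            return self.n_trees * 100
        if self.family == "latent_projection":
            return self.n_components * 13
        return 40  # 9x4 weights + 4 intercepts


def default_specs(seed: int = 0, selection_phase: bool = True) -> dict:
    """The four comparison specs (selection-phase network (50,25,25,50))."""
    hidden = (50, 25, 25, 50) if selection_phase else (100, 50, 25, 50, 100)
    return {
        "linear": ModelSpec(family="linear", seed=seed),
        "latent_projection": ModelSpec(family="latent_projection", n_components=4, seed=seed),
        "tree_ensemble": ModelSpec(family="tree_ensemble", n_trees=4, seed=seed),
        "feedforward_net": ModelSpec(family="feedforward_net", hidden_layers=hidden, seed=seed),
    }


def _build_estimator(spec: ModelSpec, seed: int):
    if spec.family == "linear":
        return LinearRegression()
    if spec.family == "latent_projection":
        return PLSRegression(n_components=spec.n_components)
    if spec.family == "tree_ensemble":
        return RandomForestRegressor(n_estimators=spec.n_trees, random_state=seed)
    return MLPRegressor(
        hidden_layer_sizes=spec.hidden_layers,
        activation=spec.activation,
        solver=spec.solver,
        alpha=spec.alpha,
        learning_rate_init=spec.learning_rate_init,
        n_iter_no_change=spec.n_iter_no_change,
        max_iter=spec.max_iter,
        tol=spec.tol,
        random_state=seed,
    )


def _weight_norm_sq(estimator) -> float:
    if hasattr(estimator, "coefs_"):  # MLP
        return float(sum(np.sum(w**2) for w in estimator.coefs_))
    if hasattr(estimator, "coef_"):
        return float(np.sum(np.asarray(estimator.coef_) ** 2))
    return 0.0


@dataclass(frozen=True)
class TrainedSurrogate:
    """A fitted multi-output regressor plus its scalers and provenance."""

    spec: ModelSpec
    estimator: object
    input_scaler: ScalerModel
    output_scaler: ScalerModel
    feature_names: tuple
    target_names: tuple
    train_min: np.ndarray
    train_max: np.ndarray
    provenance: dict = field(default_factory=dict)


def _data_hash(X: np.ndarray, Y: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X).tobytes())
    h.update(np.ascontiguousarray(Y).tobytes())
    return h.hexdigest()[:16]


def fit_surrogate(
    train_points: pd.DataFrame,
    spec: ModelSpec = ModelSpec(),
    seed: int | None = None,
    features=tuple(INPUT_FEATURES),
    targets=tuple(OUTPUT_KPIS),
) -> TrainedSurrogate:
    """Fit scalers on the training rows, then the regressor on scaled data.

    Deterministic given the seed; final regularized loss and training R²
    are recorded in the provenance dict.
    """
    seed = spec.seed if seed is None else seed
    features, targets = tuple(features), tuple(targets)
    X = train_points[list(features)].to_numpy(dtype=float)
    Y = train_points[list(targets)].to_numpy(dtype=float)
    if X.shape[0] < 20:
        raise ValueError("need at least 20 training points")
    if not np.isfinite(X).all() or not np.isfinite(Y).all():
        raise ValueError("non-finite values in training data")

    in_scaler = fit_scaler(X, features)
    out_scaler = fit_scaler(Y, targets)
    Xs, Ys = apply_scaler(in_scaler, X), apply_scaler(out_scaler, Y)
    estimator = _build_estimator(spec, seed)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*Maximum iterations.*")
        estimator.fit(Xs, Ys)

    pred = np.asarray(estimator.predict(Xs)).reshape(Ys.shape)
    penalty = PenaltySpec(alpha=spec.alpha if spec.family == "feedforward_net" else 0.0,
                          weight_norm_sq=_weight_norm_sq(estimator))
    final_loss = loss_mse_l2(PredictionPair(Ys.ravel(), pred.ravel()), penalty)
    train_r2 = float(np.mean([
        r2_score(PredictionPair(Ys[:, j], pred[:, j])) for j in range(Ys.shape[1])
    ]))
    return TrainedSurrogate(
        spec=spec,
        estimator=estimator,
        input_scaler=in_scaler,
        output_scaler=out_scaler,
        feature_names=features,
        target_names=targets,
        train_min=X.min(axis=0),
        train_max=X.max(axis=0),
        provenance={
            "seed": int(seed),
            "n_train": int(X.shape[0]),
            "data_hash": _data_hash(X, Y),
            "final_loss": final_loss,
            "train_r2": train_r2,
            "max_iter": spec.max_iter,
            "tol": spec.tol,
        },
    )


def predict_kpis(model: TrainedSurrogate, inputs):
    """Predict the 4 KPIs in physical units; flag extrapolating rows.

    ``inputs`` is a DataFrame containing the trained feature columns or an
    array in trained feature order.  Returns ``(predictions, extrapolated)``
    where predictions is an (M, 4) DataFrame and extrapolated a boolean
    vector marking rows with any input outside the training min/max.
    """
    if isinstance(inputs, pd.DataFrame):
        missing = [f for f in model.feature_names if f not in inputs.columns]
        if missing:
            raise ValueError(
                f"feature mismatch: expected {list(model.feature_names)}, "
                f"missing {missing} from {list(inputs.columns)}")
        X = inputs[list(model.feature_names)].to_numpy(dtype=float)
    else:
        X = np.atleast_2d(np.asarray(inputs, dtype=float))
        if X.shape[1] != len(model.feature_names):
            raise ValueError(
                f"feature mismatch: expected {len(model.feature_names)} columns "
                f"({list(model.feature_names)}), got {X.shape[1]}")
    Xs = apply_scaler(model.input_scaler, X)
    pred_s = np.asarray(model.estimator.predict(Xs))
    if pred_s.ndim == 1:
        pred_s = pred_s.reshape(-1, len(model.target_names))
    pred = inverse_scaler(model.output_scaler, pred_s)
    extrapolated = ((X < model.train_min) | (X > model.train_max)).any(axis=1)
    return pd.DataFrame(pred, columns=list(model.target_names)), extrapolated


def _cv_r2(points: pd.DataFrame, spec: ModelSpec, folds: int, unit: str, seed: int,
           features, targets) -> float:
    """Mean held-out R² (uniform average over the 4 outputs) across folds.

    Fold assignment is a seeded shuffle of the units (runs or rows), so
    repeated CV with different seeds samples different partitions.
    """
    rng = np.random.default_rng(seed)
    splits = []
    if unit == "run":
        units = points["run_id"].unique()
        perm = rng.permutation(len(units))
        for chunk in np.array_split(perm, folds):
            test_ids = set(units[chunk].tolist())
            mask = points["run_id"].isin(test_ids).to_numpy()
            splits.append((np.flatnonzero(~mask), np.flatnonzero(mask)))
    else:
        perm = rng.permutation(len(points))
        for chunk in np.array_split(perm, folds):
            mask = np.zeros(len(points), dtype=bool)
            mask[chunk] = True
            splits.append((np.flatnonzero(~mask), np.flatnonzero(mask)))
    scores = []
    for train_idx, test_idx in splits:
        train, test = points.iloc[train_idx], points.iloc[test_idx]
        model = fit_surrogate(train, spec, seed=seed, features=features, targets=targets)
        pred, _ = predict_kpis(model, test)
        y = test[list(targets)].to_numpy(dtype=float)
        scores.append(np.mean([
            r2_score(PredictionPair(y[:, j], pred.to_numpy()[:, j]))
            for j in range(y.shape[1])
        ]))
    return float(np.mean(scores))


@dataclass(frozen=True)
class ComparisonResult:
    """Per-family training R², CV R² and learning-curve points."""

    train_r2: dict
    cv_r2: dict
    learning_curves: dict  # family -> [(n_train, cv_r2), ...]
    folds: int


def compare_models(
    points: pd.DataFrame,
    folds: int = 3,
    specs: dict | None = None,
    unit: str = "run",
    seed: int = 0,
    features=tuple(INPUT_FEATURES),
    targets=tuple(OUTPUT_KPIS),
    learning_curve_fractions=(0.4, 0.7, 1.0),
) -> ComparisonResult:
    """Threefold (by default) cross-validated comparison of model families.

    CV folds are split at the configured unit ('run' keeps trajectories
    whole).  Learning curves refit each family on growing subsets of the
    training data of the first fold.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if unit == "run" and points["run_id"].nunique() < folds:
        raise ValueError("not enough runs for the requested folds")
    specs = specs or default_specs(seed=seed)
    train_r2, cv_r2, curves = {}, {}, {}
    for name, spec in specs.items():
        full = fit_surrogate(points, spec, seed=seed, features=features, targets=targets)
        train_r2[name] = full.provenance["train_r2"]
        cv_r2[name] = _cv_r2(points, spec, folds, unit, seed, features, targets)
        # learning curve on a fixed seeded sub-split
        rng = np.random.default_rng(seed)
        runs = points["run_id"].unique()
        perm = rng.permutation(len(runs))
        n_test = max(len(runs) // folds, 1)
        test_runs = set(runs[perm[:n_test]].tolist())
        train_pool = points[~points["run_id"].isin(test_runs)]
        test = points[points["run_id"].isin(test_runs)]
        pool_runs = train_pool["run_id"].unique()
        pts = []
        for frac in learning_curve_fractions:
            k = max(int(round(frac * len(pool_runs))), 2)
            sub = train_pool[train_pool["run_id"].isin(set(pool_runs[:k].tolist()))]
            try:
                m = fit_surrogate(sub, spec, seed=seed, features=features, targets=targets)
                pred, _ = predict_kpis(m, test)
                y = test[list(targets)].to_numpy(dtype=float)
                score = float(np.mean([
                    r2_score(PredictionPair(y[:, j], pred.to_numpy()[:, j]))
                    for j in range(y.shape[1])
                ]))
            except ValueError:
                continue
            pts.append((len(sub), score))
        curves[name] = pts
    return ComparisonResult(train_r2=train_r2, cv_r2=cv_r2,
                            learning_curves=curves, folds=folds)


def tune_hyperparameters(
    points: pd.DataFrame,
    search_space,
    folds: int = 3,
    seed: int = 0,
    unit: str = "run",
    features=tuple(INPUT_FEATURES),
    targets=tuple(OUTPUT_KPIS),
):
    """Exhaustive grid search maximizing CV R².

    ``search_space`` is an iterable of :class:`ModelSpec`.  Ties are broken
    by smaller parameter count, then lexicographic repr.  Returns
    ``(best_spec, trials)`` with the full trial table.
    """
    space = list(search_space)
    if not space:
        raise ValueError("empty search space")
    rows = []
    for spec in space:
        score = _cv_r2(points, spec, folds, unit, seed, features, targets)
        rows.append({"spec": spec, "cv_r2": score,
                     "parameter_count": spec.parameter_count})
    trials = pd.DataFrame(rows)
    best = sorted(rows, key=lambda r: (-r["cv_r2"], r["parameter_count"],
                                       repr(r["spec"])))[0]["spec"]
    return best, trials
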