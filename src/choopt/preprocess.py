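"""Cleaning, iterative feature selection, splitting and standardization.

The preprocessing chain mirrors standard practice for tabular bioprocess
data: (1) drop QC-flagged rows, (2) select model inputs by iterative
impurity-based feature importance from a tree ensemble (features whose
importance exceeds a threshold are accepted and removed from the pool,
and the ensemble is refit on the remainder until nothing clears the
threshold), (3) split 80/20 into train and test -- by whole runs by
default, so no trajectory straddles the split -- and (4) standardize with
mean/variance statistics fit on the training partition only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

__all__ = [
    "FeatureSelectionReport",
    "ScalerModel",
    "SplitSpec",
    "clean_points",
    "iterative_feature_selection",
    "split_train_test",
    "fit_scaler",
    "apply_scaler",
    "inverse_scaler",
]

log = logging.getLogger(__name__)


def clean_points(points: pd.DataFrame) -> pd.DataFrame:
    """Drop rows carrying any QC flag; surviving rows are untouched.

    The ``flags`` column holds a ``;``-joined label set (empty = clean).
    """
    if "flags" not in points.columns:
        return points.copy()
    flagged = points["flags"].fillna("").astype(str).str.len() > 0
    for _, row in points.loc[flagged].iterrows():
        log.info("removing point run=%s t=%s (%s)",
                 row.get("run_id"), row.get("process_time"), row["flags"])
    kept = points.loc[~flagged].copy()
    if kept.empty:
        warnings.warn("cleaning removed every data point", stacklevel=2)
    return kept


@dataclass(frozen=True)
class FeatureSelectionReport:
    """Record of the iterative importance analysis."""

    iterations: tuple  # one {feature: importance} dict per iteration
    selected: tuple  # ordered selected feature names
    threshold: float
    excluded_a_priori: frozenset = frozenset()


def iterative_feature_selection(
    points: pd.DataFrame,
    candidate_features,
    target: str = "titer_at_t",
    threshold: float = 0.1,
    seed: int = 0,
    excluded_a_priori=(),
    n_trees: int = 100,
) -> FeatureSelectionReport:
    """Iterative impurity-importance input selection against one target.

    Each round fits a seeded ``RandomForestRegressor`` of the remaining
    candidates on the target; candidates with importance strictly above
    ``threshold`` are appended to the selection (by descending importance,
    ties broken lexicographically) and removed from the pool.  Stops when
    no candidate clears the threshold or fewer than two remain.

    Impurity importances are relative -- they sum to one even when the
    remaining pool carries no signal at all -- so the loop works on a
    residual target in a backfitting style: after an iteration selects
    features, their out-of-bag contribution (a seeded forest on the winners
    alone) is subtracted from the working target, and each round is gated
    on the pool ensemble's out-of-bag R² against that residual.  Once the
    remaining pool no longer explains any residual signal (OOB R² <= 0)
    the loop records the iteration and stops, rather than promoting
    renormalized noise.
    """
    excluded = frozenset(excluded_a_priori)
    pool = sorted(set(candidate_features) - excluded)
    if target in pool:
        raise ValueError("target must not be among the candidate features")
    if len(pool) < 2:
        raise ValueError("need at least two candidate features")
    for col in [*pool, target]:
        if not np.issubdtype(points[col].dtype, np.number):
            raise ValueError(f"non-numeric feature column {col!r}")

    y_work = points[target].to_numpy(dtype=float).copy()
    iterations, selected = [], []
    while len(pool) >= 2:
        X = points[pool].to_numpy(dtype=float)
        forest = RandomForestRegressor(n_estimators=n_trees, random_state=seed,
                                       oob_score=True)
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message=".*out-of-bag.*")
            forest.fit(X, y_work)
        importances = dict(zip(pool, forest.feature_importances_))
        iterations.append(importances)
        oob = getattr(forest, "oob_score_", float("nan"))
        if not np.isfinite(oob) or oob <= 0.0:
            break
        winners = [f for f in pool if importances[f] > threshold]
        if not winners:
            break
        winners.sort(key=lambda f: (-importances[f], f))
        selected += winners
        pool = [f for f in pool if f not in winners]
        if pool:
            # peel the winners' contribution off the working target so the
            # next round sees only what remains to be explained
            peel = RandomForestRegressor(n_estimators=n_trees, random_state=seed,
                                         oob_score=True)
            with warnings.catch_warnings():
                warnings.filterwarnings("ignore", message=".*out-of-bag.*")
                peel.fit(points[winners].to_numpy(dtype=float), y_work)
            y_work = y_work - peel.oob_prediction_
    return FeatureSelectionReport(
        iterations=tuple(iterations),
        selected=tuple(selected),
        threshold=threshold,
        excluded_a_priori=excluded,
    )


@dataclass(frozen=True)
class SplitSpec:
    """Train/test split: fraction, unit ('run' or 'point'), seed."""

    train_fraction: float = 0.8
    unit: str = "run"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie strictly in (0, 1)")
        if self.unit not in ("run", "point"):
            raise ValueError("unit must be 'run' or 'point'")


def split_train_test(points: pd.DataFrame, spec: SplitSpec = SplitSpec()):
    """Seeded partition into (train, test).

    Unit 'run' keeps every row of a run on one side; unit 'point' splits
    rows independently.  The train side gets ``floor(train_fraction * n)``
    units.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.unit == "run":
        units = points["run_id"].unique()
    else:
        units = points.index.to_numpy()
    if len(units) < 2:
        raise ValueError("need at least two units to split")
    n_train = int(np.floor(spec.train_fraction * len(units)))
    n_train = min(max(n_train, 1), len(units) - 1)
    perm = rng.permutation(len(units))
    train_units = set(units[perm[:n_train]].tolist())
    if spec.unit == "run":
        mask = points["run_id"].isin(train_units)
    else:
        mask = points.index.isin(train_units)
    return points.loc[mask].copy(), points.loc[~mask].copy()


@dataclass(frozen=True)
class ScalerModel:
    """Per-feature standardization statistics (population std, ddof 0)."""

    feature_names: tuple
    means: np.ndarray
    stds: np.ndarray


def fit_scaler(train_matrix, feature_names=None) -> ScalerModel:
    """Fit means/stds on training rows only (population standard deviation).

    Constant columns get scale 1 (with a warning) so transforming maps
    them to exactly zero.
    """
    if isinstance(train_matrix, pd.DataFrame):
        feature_names = tuple(train_matrix.columns)
        X = train_matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(train_matrix, dtype=float)
        feature_names = tuple(feature_names or (f"x{i}" for i in range(X.shape[1])))
    means = X.mean(axis=0)
    stds = X.std(axis=0, ddof=0)
    constant = stds == 0
    if constant.any():
        names = [feature_names[i] for i in np.flatnonzero(constant)]
        warnings.warn(f"constant columns scaled with std 1: {names}", stacklevel=2)
        stds = np.where(constant, 1.0, stds)
    return ScalerModel(feature_names=feature_names, means=means, stds=stds)


def _as_array(matrix) -> np.ndarray:
    if isinstance(matrix, pd.DataFrame):
        return matrix.to_numpy(dtype=float)
    return np.asarray(matrix, dtype=float)


def apply_scaler(scaler: ScalerModel, matrix) -> np.ndarray:
    return (_as_array(matrix) - scaler.means) / scaler.stds


def inverse_scaler(scaler: ScalerModel, matrix) -> np.ndarray:
    return _as_array(matrix) * scaler.stds + scaler.means
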