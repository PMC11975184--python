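"""Core performance metrics for fed-batch cultivation modelling.

Three quantities recur throughout the analysis:

* the average cell-specific productivity Q_P, in pg antibody per cell and
  day, computed from daily titer and viable-cell-density (VCD) samples;
* the L2-regularized squared-error loss used to audit regression fits;
* the coefficient of determination R².

All three are implemented as pure functions over plain numpy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ProductivitySeries",
    "PredictionPair",
    "PenaltySpec",
    "qp_mean",
    "loss_mse_l2",
    "r2_score",
]

#: converts (g/L) / (1e6 cells/mL) into pg/cell.
#: 1 g/L = 1e9 pg / 1e6 mL; dividing by 1e6 cells/mL leaves 1e3 pg/cell.
UNIT_FACTOR_PG_PER_CELL = 1000.0


@dataclass(frozen=True)
class ProductivitySeries:
    """Daily titer (g/L) and VCD (1e6 cells/mL) trajectories of one run.

    ``titers[n]`` and ``vcds[n]`` are the day-``n`` samples; ``dt`` is the
    sampling interval in days (1 for daily sampling).
    """

    titers: np.ndarray
    vcds: np.ndarray
    dt: float = 1.0

    def __post_init__(self) -> None:
        t = np.asarray(self.titers, dtype=float)
        v = np.asarray(self.vcds, dtype=float)
        object.__setattr__(self, "titers", t)
        object.__setattr__(self, "vcds", v)
        if t.ndim != 1 or v.ndim != 1 or t.shape != v.shape:
            raise ValueError("titers and vcds must be 1-D arrays of equal length")
        if t.size < 2:
            raise ValueError("need at least two samples to form a productivity")
        if not self.dt > 0:
            raise ValueError("dt must be positive")


@dataclass(frozen=True)
class PredictionPair:
    """A matched (true, predicted) value pair for regression metrics."""

    y_true: np.ndarray
    y_pred: np.ndarray

    def __post_init__(self) -> None:
        yt = np.asarray(self.y_true, dtype=float).ravel()
        yp = np.asarray(self.y_pred, dtype=float).ravel()
        object.__setattr__(self, "y_true", yt)
        object.__setattr__(self, "y_pred", yp)
        if yt.size != yp.size:
            raise ValueError("y_true and y_pred lengths differ")
        if yt.size == 0:
            raise ValueError("empty prediction pair")

    @property
    def n(self) -> int:
        return int(self.y_true.size)


@dataclass(frozen=True)
class PenaltySpec:
    """L2 penalty: weight ``alpha`` times the squared weight norm."""

    alpha: float = 0.0
    weight_norm_sq: float = 0.0

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.weight_norm_sq < 0:
            raise ValueError("alpha and weight_norm_sq must be non-negative")


def qp_mean(series: ProductivitySeries) -> float:
    """Average productivity per cell and day, pg/(cell*day).

    Q_P = (1/N) * sum_{n=1..N} (IgG_n - IgG_{n-1}) /
          (((VCD_{n-1} + VCD_n)/2) * dt)

    with N = len(series) - 1 and the 1000x unit factor making g/L and
    1e6 cells/mL yield pg/(cell*day).  For the full 13-day process N = 12.
    """
    t, v, dt = series.titers, series.vcds, series.dt
    vcd_avg = (v[:-1] + v[1:]) / 2.0
    if np.any(vcd_avg <= 0):
        bad = int(np.argmax(vcd_avg <= 0)) + 1
        raise ValueError(f"non-positive averaged VCD entering denominator at day {bad}")
    increments = np.diff(t)
    n = t.size - 1
    return float(np.sum(increments / (vcd_avg * dt)) / n * UNIT_FACTOR_PG_PER_CELL)


def loss_mse_l2(pair: PredictionPair, penalty: PenaltySpec = PenaltySpec()) -> float:
    """Regularized squared loss L = (1/2n)*SSE + (alpha/2n)*||W||^2."""
    n = pair.n
    sse = float(np.sum((pair.y_pred - pair.y_true) ** 2))
    return sse / (2.0 * n) + penalty.alpha * penalty.weight_norm_sq / (2.0 * n)


def r2_score(pair: PredictionPair) -> float:
    """Coefficient of determination R² = 1 - SSE/SST.

    Best value is 1.0; a model predicting the mean scores 0.0; arbitrarily
    worse models score negative.  Undefined (raises) for constant y_true.
    """
    if pair.n < 2:
        raise ValueError("R^2 needs at least two samples")
    y, yhat = pair.y_true, pair.y_pred
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        raise ValueError("R^2 undefined: y_true is constant (zero total sum of squares)")
    sse = float(np.sum((y - yhat) ** 2))
    return 1.0 - sse / sst
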