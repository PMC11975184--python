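"""In-silico screening of candidate process settings through a surrogate.

A large candidate matrix of process-input combinations is sampled
uniformly within the training-data ranges (the surrogate is not trusted
far outside the data it saw), the four KPIs are predicted for every
candidate, candidates whose predicted titer clears a threshold survive,
survivors are ranked per KPI, and a small, mutually dissimilar set of
proposals is selected per KPI for validation.  Validation replaces the
wet lab with the ground-truth simulator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datastore import INPUT_FEATURES, OUTPUT_KPIS
from .metrics import ProductivitySeries, qp_mean
from .models import TrainedSurrogate, predict_kpis
from .preprocess import apply_scaler
from .simulator import (
    NONE_DAY,
    CultivationRun,
    ProcessCondition,
    SimulatorParams,
    child_seed,
    simulate_run,
)

__all__ = [
    "CandidateSpace",
    "ScreeningResult",
    "generate_candidates",
    "screen",
    "select_proposals",
    "validate_in_silico",
    "run_kpis",
]

#: roman-numeral block label per KPI (I: VCD_max, II: titer, III: diameter, IV: Q_P).
KPI_BLOCKS = {
    "vcd_max_to_t": "I",
    "titer_at_t": "II",
    "diameter_max_to_t": "III",
    "qp_mean_to_t": "IV",
}

CONTINUOUS_INPUTS = ("ph_setpoint", "do_setpoint", "vcd0", "glc_start", "gln_start")
DISCRETE_INPUTS = ("glc_feed_target", "feed_start_day", "ph_shift_day", "process_time")


@dataclass(frozen=True)
class CandidateSpace:
    """Sampling domain for the nine inputs.

    Continuous inputs get [min, max] bounds (taken from training data and
    clamped to it); discrete inputs are drawn uniformly from their
    observed value sets.
    """

    continuous: dict  # name -> (lo, hi)
    discrete: dict  # name -> tuple of values
    m: int = 1_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("candidate count m must be >= 1")
        for name, (lo, hi) in self.continuous.items():
            if lo > hi:
                raise ValueError(f"inverted bounds for {name}")
        for name, values in self.discrete.items():
            if len(values) == 0:
                raise ValueError(f"empty discrete set for {name}")

    @classmethod
    def from_training_data(cls, train_points: pd.DataFrame, m: int = 1_000_000,
                           seed: int = 0) -> "CandidateSpace":
        continuous = {
            name: (float(train_points[name].min()), float(train_points[name].max()))
            for name in CONTINUOUS_INPUTS
        }
        discrete = {
            name: tuple(sorted(train_points[name].unique().tolist()))
            for name in DISCRETE_INPUTS
        }
        return cls(continuous=continuous, discrete=discrete, m=m, seed=seed)


def generate_candidates(space: CandidateSpace) -> pd.DataFrame:
    """Sample ``space.m`` candidate rows uniformly, seeded."""
    rng = np.random.default_rng(space.seed)
    cols = {}
    for name in INPUT_FEATURES:
        if name in space.continuous:
            lo, hi = space.continuous[name]
            cols[name] = rng.uniform(lo, hi, size=space.m)
        else:
            values = np.asarray(space.discrete[name], dtype=float)
            cols[name] = values[rng.integers(0, len(values), size=space.m)]
    return pd.DataFrame(cols, columns=INPUT_FEATURES)


@dataclass(frozen=True)
class ScreeningResult:
    """Survivors of the titer filter with per-KPI rankings."""

    survivors: pd.DataFrame  # inputs + pred_<kpi> columns + extrapolated + candidate_index
    threshold: float
    n_candidates: int
    rankings: dict  # kpi -> np.ndarray of survivor positional indices, best first

    @property
    def survivor_fraction(self) -> float:
        return len(self.survivors) / self.n_candidates

    def day12_fraction(self, kpi: str = "titer_at_t", top: int = 100) -> float:
        """Diagnostic: fraction of the top-`top` survivors (by the given
        KPI) whose process-time input is day 12."""
        idx = self.rankings[kpi][:top]
        if len(idx) == 0:
            return float("nan")
        pt = self.survivors.iloc[idx]["process_time"].to_numpy()
        return float(np.mean(pt == 12.0))


def screen(model: TrainedSurrogate, candidates: pd.DataFrame,
           threshold: float = 4.6, batch_size: int = 100_000) -> ScreeningResult:
    """Predict KPIs for every candidate and keep predicted titer > threshold.

    Survivors carry their original candidate index; per-KPI rankings are
    descending with ties broken by ascending candidate index.
    """
    preds, flags = [], []
    for start in range(0, len(candidates), batch_size):
        chunk = candidates.iloc[start:start + batch_size]
        p, f = predict_kpis(model, chunk)
        preds.append(p)
        flags.append(f)
    pred = pd.concat(preds, ignore_index=True)
    extrapolated = np.concatenate(flags)
    values = pred.to_numpy()
    if not np.isfinite(values).all():
        bad = np.flatnonzero(~np.isfinite(values).all(axis=1))
        raise ValueError(f"non-finite predictions at candidate rows {bad[:10].tolist()}")

    keep = pred["titer_at_t"].to_numpy() > threshold
    survivors = candidates.loc[keep].reset_index(drop=True).copy()
    survivors["candidate_index"] = np.flatnonzero(keep)
    for kpi in OUTPUT_KPIS:
        survivors[f"pred_{kpi}"] = pred.loc[keep, kpi].to_numpy()
    survivors["extrapolated"] = extrapolated[keep]

    rankings = {}
    for kpi in OUTPUT_KPIS:
        vals = survivors[f"pred_{kpi}"].to_numpy()
        # descending value, ascending candidate index on ties
        order = np.lexsort((survivors["candidate_index"].to_numpy(), -vals))
        rankings[kpi] = order
    return ScreeningResult(survivors=survivors, threshold=threshold,
                           n_candidates=len(candidates), rankings=rankings)


def _greedy_maxmin(scaled: np.ndarray, picks: int) -> list:
    """Greedy max-min-distance subset, starting from row 0 (the top rank).

    Each step adds the point maximizing the minimum distance to the
    chosen set; ties break toward the better (lower) rank.
    """
    chosen = [0]
    while len(chosen) < picks:
        dists = np.full(len(scaled), np.inf)
        for c in chosen:
            dists = np.minimum(dists, np.linalg.norm(scaled - scaled[c], axis=1))
        dists[chosen] = -np.inf
        best = int(np.argmax(dists))  # argmax takes the first (best-ranked) tie
        chosen.append(best)
    return chosen


def select_proposals(result: ScreeningResult, model: TrainedSurrogate,
                     per_kpi_pool: int = 10, picks: dict | None = None) -> pd.DataFrame:
    """Diverse proposals from each KPI's top-ranked survivors.

    From the top ``per_kpi_pool`` survivors of each KPI ranking, greedily
    pick ``picks[kpi]`` (default 4; 5 for titer) maximizing the minimum
    pairwise distance in scaled input space, starting from the top-ranked
    candidate.  Returns a block-labelled proposal frame (I/II/III/IV by KPI).
    """
    picks = picks or {kpi: (5 if kpi == "titer_at_t" else 4) for kpi in OUTPUT_KPIS}
    frames = []
    for kpi in OUTPUT_KPIS:
        k = picks.get(kpi, 4)
        pool_idx = result.rankings[kpi][:per_kpi_pool]
        if len(pool_idx) < per_kpi_pool:
            raise ValueError(
                f"only {len(pool_idx)} survivors for {kpi}; lower per_kpi_pool "
                f"(requested {per_kpi_pool})")
        pool = result.survivors.iloc[pool_idx].reset_index(drop=True)
        scaled = apply_scaler(model.input_scaler,
                              pool[list(model.feature_names)])
        if np.allclose(scaled, scaled[0]):
            warnings.warn(f"identical candidates in {kpi} pool; separation 0",
                          stacklevel=2)
            chosen = list(range(min(k, len(pool))))
        else:
            chosen = _greedy_maxmin(scaled, min(k, len(pool)))
        sub = pool.iloc[chosen].copy()
        sub.insert(0, "block", KPI_BLOCKS[kpi])
        sub.insert(1, "name", [f"{KPI_BLOCKS[kpi]} {chr(ord('a') + i)}"
                               for i in range(len(sub))])
        sub.insert(2, "target_kpi", kpi)
        frames.append(sub)
    return pd.concat(frames, ignore_index=True)


def run_kpis(run: CultivationRun) -> dict:
    """The four whole-run KPIs of a simulated cultivation."""
    diams = np.array([s.diameter for s in run.samples])
    return {
        "vcd_max_to_t": run.vcd_max,
        "titer_at_t": run.final_titer,
        "diameter_max_to_t": float(diams.max()),
        "qp_mean_to_t": qp_mean(ProductivitySeries(run.titers, run.vcds)),
    }


def condition_from_row(row, ph_shift_value: float = 7.4) -> ProcessCondition:
    """Rebuild a ProcessCondition from a flat candidate/proposal row."""
    return ProcessCondition(
        ph_setpoint=float(row["ph_setpoint"]),
        do_setpoint=float(row["do_setpoint"]),
        vcd0=float(row["vcd0"]),
        glc_start=float(row["glc_start"]),
        gln_start=float(row["gln_start"]),
        glc_feed_target=float(row["glc_feed_target"]),
        feed_start_day=int(row["feed_start_day"]),
        ph_shift_day=int(row["ph_shift_day"]),
        ph_shift_value=ph_shift_value,
    )


def validate_in_silico(
    proposals: pd.DataFrame,
    truth_params: SimulatorParams,
    n_std_replicates: int = 3,
    seed: int = 0,
    std_condition: ProcessCondition = ProcessCondition(),
    ph_shift_value: float = 7.4,
) -> pd.DataFrame:
    """Simulate each proposal plus standard-condition replicates.

    The ground-truth simulator stands in for the wet-lab validation runs.
    Returns one row per proposal with predicted vs validated KPIs and the
    percent change of each validated KPI against the mean validated
    standard run.
    """
    std_kpis = []
    for r in range(n_std_replicates):
        run = simulate_run(std_condition, truth_params,
                           seed=child_seed(seed, 90_000 + r), run_id=f"STD_{r}")
        std_kpis.append(run_kpis(run))
    std_mean = {k: float(np.mean([d[k] for d in std_kpis])) for k in OUTPUT_KPIS}

    rows = []
    for i, (_, prop) in enumerate(proposals.iterrows()):
        cond = condition_from_row(prop, ph_shift_value=ph_shift_value)
        run = simulate_run(cond, truth_params, seed=child_seed(seed, i),
                           run_id=str(prop.get("name", f"prop_{i}")))
        validated = run_kpis(run)
        row = {c: prop[c] for c in proposals.columns}
        for kpi in OUTPUT_KPIS:
            row[f"valid_{kpi}"] = validated[kpi]
            row[f"std_{kpi}"] = std_mean[kpi]
            if f"pred_{kpi}" in proposals.columns:
                row[f"dev_{kpi}"] = abs(prop[f"pred_{kpi}"] - validated[kpi])
            row[f"pct_change_{kpi}"] = (
                (validated[kpi] - std_mean[kpi]) / std_mean[kpi] * 100.0
            )
        rows.append(row)
    return pd.DataFrame(rows)
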