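"""End-to-end orchestration: simulate -> store -> preprocess -> train ->
screen -> validate in silico -> report.

``run_pipeline`` executes the whole loop from a single seeded config and
returns (and optionally persists) every stage artifact plus a headline
summary: the best validated titer against the standard process, the
percent increase, and the prediction deviation.  ``make_comparison_report``
renders the predicted/validated/standard comparison for one condition.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import datastore, preprocess, screening, simulator
from .datastore import INPUT_FEATURES, OUTPUT_KPIS
from .models import ModelSpec, TrainedSurrogate, fit_surrogate
from .preprocess import SplitSpec
from .simulator import SimulatorParams

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline", "make_comparison_report"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one optimization loop needs, round-trippable to JSON."""

    seed: int = 0
    design_kind: str = "FULL_58"
    noise_cv: float = 0.05
    flag_fraction: float = 19 / 754  # the expected QC-failure rate
    fs_threshold: float = 0.1
    excluded_a_priori: tuple = ()
    split: SplitSpec = field(default_factory=SplitSpec)
    model_spec: ModelSpec = field(default_factory=ModelSpec)
    n_candidates: int = 100_000
    titer_threshold: float = 4.6
    per_kpi_pool: int = 10
    titer_picks: int = 5
    other_picks: int = 4
    ph_shift_value: float = 7.4
    n_std_replicates: int = 3
    outputs_mode: str = "running"

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["split"] = dataclasses.asdict(self.split)
        d["model_spec"] = dataclasses.asdict(self.model_spec)
        return json.dumps(d, sort_keys=True, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        d = json.loads(text)
        d["split"] = SplitSpec(**d["split"])
        ms = d["model_spec"]
        ms["hidden_layers"] = tuple(ms["hidden_layers"])
        d["model_spec"] = ModelSpec(**ms)
        d["excluded_a_priori"] = tuple(d.get("excluded_a_priori", ()))
        return cls(**d)


@dataclass
class PipelineReport:
    """Artifacts of one full optimization loop."""

    config: PipelineConfig
    counts: dict
    selection: preprocess.FeatureSelectionReport
    surrogate: TrainedSurrogate
    screening: screening.ScreeningResult
    proposals: pd.DataFrame
    validation: pd.DataFrame
    headline: dict


def run_pipeline(config: PipelineConfig, outdir=None) -> PipelineReport:
    """Execute all stages in order with seeds derived from config.seed."""
    seed = config.seed
    params = SimulatorParams(noise_cv=config.noise_cv)

    log.info("stage 1: simulating %s design", config.design_kind)
    design = simulator.build_design(config.design_kind)
    runs = simulator.generate_dataset(design, params, seed=seed,
                                      flag_fraction=config.flag_fraction)

    log.info("stage 2: flattening %d runs", len(runs))
    points = datastore.flatten_to_points(runs, outputs=config.outputs_mode)
    n_raw = len(points)
    cleaned = preprocess.clean_points(points)
    counts = {"runs": len(runs), "points": n_raw, "cleaned": len(cleaned),
              "removed": n_raw - len(cleaned)}
    log.info("stage 2: %(points)d points, %(removed)d flagged, %(cleaned)d kept",
             counts)

    log.info("stage 3: feature selection")
    selection = preprocess.iterative_feature_selection(
        cleaned, INPUT_FEATURES, target="titer_at_t",
        threshold=config.fs_threshold, seed=seed,
        excluded_a_priori=config.excluded_a_priori)

    log.info("stage 4: split + train surrogate (%s)", config.model_spec.family)
    split_spec = dataclasses.replace(config.split, seed=seed)
    train, test = preprocess.split_train_test(cleaned, split_spec)
    surrogate = fit_surrogate(train, config.model_spec, seed=seed)
    counts["train"], counts["test"] = len(train), len(test)

    log.info("stage 5: screening %d candidates", config.n_candidates)
    space = screening.CandidateSpace.from_training_data(
        train, m=config.n_candidates, seed=seed)
    candidates = screening.generate_candidates(space)
    result = screening.screen(surrogate, candidates,
                              threshold=config.titer_threshold)
    counts["survivors"] = len(result.survivors)
    log.info("stage 5: %d survivors (%.3f%%)", counts["survivors"],
             100 * result.survivor_fraction)

    picks = {kpi: (config.titer_picks if kpi == "titer_at_t" else config.other_picks)
             for kpi in OUTPUT_KPIS}
    proposals = screening.select_proposals(result, surrogate,
                                           per_kpi_pool=config.per_kpi_pool,
                                           picks=picks)

    log.info("stage 6: in-silico validation of %d proposals", len(proposals))
    validation = screening.validate_in_silico(
        proposals, params, n_std_replicates=config.n_std_replicates,
        seed=simulator.child_seed(seed, 777), ph_shift_value=config.ph_shift_value)

    best = validation.loc[validation["valid_titer_at_t"].idxmax()]
    std_titer = float(best["std_titer_at_t"])
    headline = {
        "best_validated_titer": float(best["valid_titer_at_t"]),
        "best_run_name": str(best["name"]),
        "std_validated_titer": std_titer,
        "abs_titer_increase": float(best["valid_titer_at_t"]) - std_titer,
        "pct_titer_increase": (float(best["valid_titer_at_t"]) - std_titer)
        / std_titer * 100.0,
        "prediction_deviation": float(best["dev_titer_at_t"]),
        "day12_fraction_top_titer": result.day12_fraction(),
        "titer_block_median_validated": float(
            validation.loc[validation["block"] == "II", "valid_titer_at_t"].median()),
    }
    report = PipelineReport(config=config, counts=counts, selection=selection,
                            surrogate=surrogate, screening=result,
                            proposals=proposals, validation=validation,
                            headline=headline)
    if outdir is not None:
        _persist(report, Path(outdir))
    return report


def _persist(report: PipelineReport, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.json").write_text(report.config.to_json())
    (outdir / "counts.json").write_text(json.dumps(report.counts, indent=2))
    (outdir / "headline.json").write_text(json.dumps(report.headline, indent=2))
    sel = {
        "threshold": report.selection.threshold,
        "selected": list(report.selection.selected),
        "iterations": [dict(it) for it in report.selection.iterations],
    }
    (outdir / "feature_selection.json").write_text(json.dumps(sel, indent=2))
    report.proposals.to_csv(outdir / "proposals.csv", index=False)
    report.validation.to_csv(outdir / "validation.csv", index=False)


def make_comparison_report(prediction: dict, validation: dict, std_stats: dict) -> pd.DataFrame:
    """Predicted / validated / standard comparison for one condition.

    ``prediction`` and ``validation`` map KPI name -> value for the
    proposed condition; ``std_stats`` maps KPI name -> validated standard
    value.  Percent increase is (validated - std)/std * 100; prediction
    deviation is |predicted - validated| with the percent form taken
    against the predicted value.
    """
    rows = []
    for kpi in prediction:
        if kpi not in validation or kpi not in std_stats:
            raise ValueError(f"missing KPI {kpi!r} in validation or standard stats")
        pred, valid, std = prediction[kpi], validation[kpi], std_stats[kpi]
        rows.append({
            "kpi": kpi,
            "predicted": pred,
            "validated": valid,
            "std_validated": std,
            "abs_increase_vs_std": valid - std,
            "pct_increase_vs_std": (valid - std) / std * 100.0,
            "prediction_deviation": abs(pred - valid),
            "prediction_deviation_pct": abs(pred - valid) / pred * 100.0,
        })
    return pd.DataFrame(rows)
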