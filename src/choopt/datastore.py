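"""Schema-validated JSON persistence and the flat model-ready table.

Cultivation runs are stored one JSON document per run (newline-delimited
collection files), constrained by the JSON-schema document shipped at
``choopt/data/run_record_schema.json``.  The flat table used by the
machine-learning stages has one row per (run, day): nine numeric inputs
(the eight run-level setpoints plus process time) and four key performance
indicators (KPIs) computed as *running* statistics of the trajectory up to
that day.

Field names are reconstructed from the process description (the original
database schema is not public); the shipped schema says so in its
``description`` fields.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .metrics import ProductivitySeries, qp_mean
from .simulator import CultivationRun, DailySample, ProcessCondition

__all__ = [
    "INPUT_FEATURES",
    "OUTPUT_KPIS",
    "FormatError",
    "ValidationReport",
    "run_record_schema",
    "validate_record",
    "run_to_record",
    "record_to_run",
    "save_runs",
    "load_runs",
    "flatten_to_points",
    "points_to_csv",
]

#: canonical model-input column order (process time last).
INPUT_FEATURES = [
    "do_setpoint",
    "ph_setpoint",
    "gln_start",
    "glc_start",
    "ph_shift_day",
    "vcd0",
    "feed_start_day",
    "glc_feed_target",
    "process_time",
]

#: the four KPIs, as running statistics up to the row's process time.
OUTPUT_KPIS = ["vcd_max_to_t", "titer_at_t", "diameter_max_to_t", "qp_mean_to_t"]

_CONDITION_FIELDS = [
    "ph_setpoint", "do_setpoint", "vcd0", "glc_start", "gln_start",
    "glc_feed_target", "feed_start_day", "ph_shift_day", "ph_shift_value",
]

_SAMPLE_FIELDS = ["day", "vcd", "viability", "diameter", "glc", "gln", "lac", "titer"]


class FormatError(ValueError):
    """The document is not parseable JSON (distinct from schema failure)."""


@dataclass(frozen=True)
class ValidationReport:
    ok: bool
    violations: tuple = ()  # (json_path, message) pairs

    def __bool__(self) -> bool:
        return self.ok


def run_record_schema() -> dict:
    """The JSON-schema document constraining one run record."""
    text = resources.files("choopt.data").joinpath("run_record_schema.json").read_text()
    return json.loads(text)


# -- minimal schema checker -------------------------------------------------
# Covers the subset of JSON-schema keywords the shipped schema uses:
# type, required, properties, items, minItems, maxItems, minimum, maximum,
# exclusiveMinimum, enum.

_TYPES = {
    "object": dict,
    "array": list,
    "string": str,
    "number": (int, float),
    "integer": int,
    "boolean": bool,
}


def _check(node, schema: dict, path: str, out: list) -> None:
    expected = schema.get("type")
    if expected is not None:
        py = _TYPES[expected]
        ok = isinstance(node, py) and not (expected in ("number", "integer")
                                           and isinstance(node, bool))
        if expected == "number" and isinstance(node, bool):
            ok = False
        if not ok:
            out.append((path, f"expected type {expected}"))
            return
    if "enum" in schema and node not in schema["enum"]:
        out.append((path, f"value {node!r} not in enum"))
    if isinstance(node, (int, float)) and not isinstance(node, bool):
        if "minimum" in schema and node < schema["minimum"]:
            out.append((path, f"value {node} below minimum {schema['minimum']}"))
        if "maximum" in schema and node > schema["maximum"]:
            out.append((path, f"value {node} above maximum {schema['maximum']}"))
        if "exclusiveMinimum" in schema and node <= schema["exclusiveMinimum"]:
            out.append((path, f"value {node} not above {schema['exclusiveMinimum']}"))
    if isinstance(node, dict):
        for key in schema.get("required", []):
            if key not in node:
                out.append((f"{path}.{key}", "required key missing"))
        for key, sub in schema.get("properties", {}).items():
            if key in node:
                _check(node[key], sub, f"{path}.{key}", out)
    if isinstance(node, list):
        if "minItems" in schema and len(node) < schema["minItems"]:
            out.append((path, f"fewer than {schema['minItems']} items"))
        if "maxItems" in schema and len(node) > schema["maxItems"]:
            out.append((path, f"more than {schema['maxItems']} items"))
        if "items" in schema:
            for i, item in enumerate(node):
                _check(item, schema["items"], f"{path}[{i}]", out)


def validate_record(document, schema: dict | None = None) -> ValidationReport:
    """Validate one run record against the schema.

    ``document`` may be a dict or a JSON string.  Unparseable input raises
    :class:`FormatError`; schema violations are *returned*, each with the
    JSON path of the offending node.
    """
    if isinstance(document, (str, bytes)):
        try:
            document = json.loads(document)
        except json.JSONDecodeError as exc:
            raise FormatError(f"not parseable JSON: {exc}") from exc
    schema = schema or run_record_schema()
    violations: list = []
    _check(document, schema, "$", violations)
    return ValidationReport(ok=not violations, violations=tuple(violations))


# -- run <-> record conversion ---------------------------------------------

def run_to_record(run: CultivationRun) -> dict:
    return {
        "run_id": run.run_id,
        "condition": {k: getattr(run.condition, k) for k in _CONDITION_FIELDS},
        "samples": [
            {**{k: getattr(s, k) for k in _SAMPLE_FIELDS},
             "flags": sorted(s.flags)}
            for s in run.samples
        ],
        "flags": sorted(run.flags),
        "metadata": dict(run.metadata),
    }


def record_to_run(record: dict) -> CultivationRun:
    cond = ProcessCondition(**record["condition"])
    samples = tuple(
        DailySample(**{k: s[k] for k in _SAMPLE_FIELDS},
                    flags=frozenset(s.get("flags", [])))
        for s in record["samples"]
    )
    return CultivationRun(
        run_id=record["run_id"],
        condition=cond,
        samples=samples,
        flags=frozenset(record.get("flags", [])),
        metadata=dict(record.get("metadata", {})),
    )


def save_runs(path, runs) -> None:
    """Write runs as newline-delimited JSON records (sorted keys)."""
    with open(path, "w") as fh:
        for run in runs:
            fh.write(json.dumps(run_to_record(run), sort_keys=True) + "\n")


def load_runs(path) -> list:
    runs = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                runs.append(record_to_run(json.loads(line)))
    return runs


# -- flattening -------------------------------------------------------------

def flatten_to_points(runs, outputs: str = "running") -> pd.DataFrame:
    """One row per (run, day) with the 9 inputs and 4 KPI outputs.

    ``outputs='running'`` (default) computes time-resolved KPIs over the
    trajectory up to each row's process time: running max VCD, the titer
    at that day, running max diameter, and the mean cell-specific
    productivity over days 1..t (0 at day 0).  ``outputs='whole_run'``
    repeats the full-run KPIs on every row instead.
    """
    if outputs not in ("running", "whole_run"):
        raise ValueError("outputs must be 'running' or 'whole_run'")
    rows = []
    for run in runs:
        days = [s.day for s in run.samples]
        if days != list(range(len(days))):
            missing = sorted(set(range(max(days) + 1)) - set(days))
            raise ValueError(f"run {run.run_id} has gaps at days {missing}")
        cond = run.condition
        titers, vcds = run.titers, run.vcds
        diams = np.array([s.diameter for s in run.samples])
        for t, sample in enumerate(run.samples):
            if outputs == "running":
                hi = t
            else:
                hi = len(run.samples) - 1
            qp = 0.0
            if hi >= 1:
                qp = qp_mean(ProductivitySeries(titers[: hi + 1], vcds[: hi + 1]))
            rows.append({
                "run_id": run.run_id,
                "do_setpoint": cond.do_setpoint,
                "ph_setpoint": cond.ph_setpoint,
                "gln_start": cond.gln_start,
                "glc_start": cond.glc_start,
                "ph_shift_day": float(cond.ph_shift_day),
                "vcd0": cond.vcd0,
                "feed_start_day": float(cond.feed_start_day),
                "glc_feed_target": cond.glc_feed_target,
                "process_time": float(t),
                "vcd_max_to_t": float(vcds[: hi + 1].max()),
                "titer_at_t": float(titers[hi]),
                "diameter_max_to_t": float(diams[: hi + 1].max()),
                "qp_mean_to_t": qp,
                "flags": ";".join(sorted(run.flags | sample.flags)),
            })
    return pd.DataFrame(rows, columns=["run_id", *INPUT_FEATURES, *OUTPUT_KPIS, "flags"])


def points_to_csv(points: pd.DataFrame, path) -> None:
    points.to_csv(Path(path), index=False)
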