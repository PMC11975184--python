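#!/usr/bin/env python
"""Render the predicted/validated/standard comparison for the best run.

Reads the validation table produced by 04_optimize_in_silico.py and prints
the per-KPI comparison of the best-titer proposal against the standard
process, with absolute and percent deviations.
"""

import argparse
from pathlib import Path

import pandas as pd

from choopt.datastore import OUTPUT_KPIS
from choopt.pipeline import make_comparison_report

LABELS = {
    "vcd_max_to_t": "VCD_max [1e6 cells/mL]",
    "titer_at_t": "final mAb titer [g/L]",
    "diameter_max_to_t": "max cell diameter [um]",
    "qp_mean_to_t": "Q_P [pg/(cell*day)]",
}


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--validation", type=Path,
                    default=Path("results/optimization/validation.csv"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    table = pd.read_csv(args.validation)
    best = table.loc[table["valid_titer_at_t"].idxmax()]
    print(f"best run: {best['name']} "
          f"(pH {best['ph_setpoint']:.2f}, DO {best['do_setpoint']:.0f}%, "
          f"VCD0 {best['vcd0']:.2f}, Glc {best['glc_start']:.1f} g/L, "
          f"Gln {best['gln_start']:.1f} mM, feed to {best['glc_feed_target']:.0f} g/L "
          f"from day {best['feed_start_day']:.0f}, "
          f"pH shift day {best['ph_shift_day']:.0f})\n")

    report = make_comparison_report(
        prediction={k: best[f"pred_{k}"] for k in OUTPUT_KPIS},
        validation={k: best[f"valid_{k}"] for k in OUTPUT_KPIS},
        std_stats={k: best[f"std_{k}"] for k in OUTPUT_KPIS})
    report["kpi"] = report["kpi"].map(LABELS)
    with pd.option_context("display.width", 120):
        print(report.round(2).to_string(index=False))

    out = args.outdir / "best_run_report.csv"
    report.to_csv(out, index=False)
    print(f"\nwrote {out}")


if __name__ == "__main__":
    main()
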