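#!/usr/bin/env python
"""Compare the four surrogate families under threefold cross-validation.

Linear regression, partial-least-squares projection, a small random
forest, and the multilayer perceptron are fit to the cleaned point table;
CV folds keep whole cultivation runs together.
"""

import argparse
from pathlib import Path

import pandas as pd

from choopt.models import compare_models, default_specs
from choopt.preprocess import clean_points


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--points", type=Path, default=Path("results/points.csv"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    cleaned = clean_points(pd.read_csv(args.points, keep_default_na=False))
    res = compare_models(cleaned, folds=3, seed=args.seed,
                         specs=default_specs(seed=args.seed, selection_phase=False))

    rows = []
    for family in res.cv_r2:
        rows.append({"family": family,
                     "train_r2": round(res.train_r2[family], 3),
                     "cv_r2": round(res.cv_r2[family], 3)})
        print(f"{family:20s} train R2 {res.train_r2[family]:.3f}   "
              f"CV R2 {res.cv_r2[family]:.3f}")
    best = max(res.cv_r2, key=res.cv_r2.get)
    print(f"best family by held-out R2: {best}")

    out = args.outdir / "model_comparison.csv"
    pd.DataFrame(rows).to_csv(out, index=False)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
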