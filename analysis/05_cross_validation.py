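#!/usr/bin/env python
"""Out-of-sample validation of the spatial mixed scaling model.

Stratified 70/30 split by level; the model is fitted to the training set and
predicts held-out ln A from fixed effects plus the best linear predictor of
the random/spatial parts given the training residuals.
"""

import argparse
import dataclasses
from pathlib import Path

import pandas as pd

from polityscale.io import read_society_table, write_report
from polityscale.spatial import ModelSpec, cross_validate


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--input", type=Path, default=Path("results/societies.csv"))
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    parser.add_argument("--train-fraction", type=float, default=0.7)
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    table, _ = read_society_table(args.input)
    args.outdir.mkdir(parents=True, exist_ok=True)

    cv = cross_validate(
        table, ModelSpec(), train_fraction=args.train_fraction, seed=args.seed
    )
    print(
        f"train: n = {cv.n_train}, R2 (corr^2) = {cv.train_r2:.3f}, "
        f"R2 (1-SSE/SST) = {cv.train_r2_sse:.3f}"
    )
    print(
        f" test: n = {cv.n_test}, R2 (corr^2) = {cv.test_r2:.3f}, "
        f"R2 (1-SSE/SST) = {cv.test_r2_sse:.3f}"
    )
    print(
        "in-sample fit exceeds out-of-sample prediction: "
        f"{cv.test_r2 < cv.train_r2}"
    )
    write_report(pd.DataFrame([dataclasses.asdict(cv)]), args.outdir / "crossval.csv")


if __name__ == "__main__":
    main()
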