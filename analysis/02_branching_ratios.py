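#!/usr/bin/env python
"""Branching-ratio analysis: per-level summaries, Horton fits, beta prediction.

Reads results/societies.csv (run 01_generate_data.py first, or point --input
at any society table), computes per-level lognormal summaries with geometric
means and 95% CLs, adjacent branching ratios, the semi-log self-similarity
fits for N, A and D, the predicted allometric exponent beta = gamma/lam, and
per-quantile growth rates. Writes tables under results/ and a means-vs-level
figure under results/figures/.
"""

import argparse
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from polityscale.branching import (
    branching_ratios_adjacent,
    density_fit,
    fit_horton_law,
    level_summaries,
    predict_beta,
    quantile_horton_fit,
)
from polityscale.io import read_society_table, write_report


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--input", type=Path, default=Path("results/societies.csv"))
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    args = parser.parse_args()

    table, _ = read_society_table(args.input)
    args.outdir.mkdir(parents=True, exist_ok=True)

    summaries = {m: level_summaries(table, m) for m in ("N", "A", "D")}
    rows = [s.to_row() for m in summaries for s in summaries[m]]
    write_report(pd.DataFrame(rows), args.outdir / "level_summaries.csv")

    fits = {
        "N": fit_horton_law(summaries["N"]),
        "A": fit_horton_law(summaries["A"]),
    }
    fits["D"] = density_fit(fits["N"], fits["A"], summaries["D"])
    write_report(
        pd.DataFrame([f.to_row() for f in fits.values()]),
        args.outdir / "horton_fits.csv",
    )

    label = {"N": "population size", "A": "geographic range", "D": "density"}
    for m, fit in fits.items():
        print(
            f"{label[m]:>17}: rate {fit.slope:+.3f}  branching ratio "
            f"{fit.branching_ratio:.2f} ({fit.ratio_ci_lower:.2f}-"
            f"{fit.ratio_ci_upper:.2f})  R2 {fit.r_squared:.3f}  "
            f"self-similar: {fit.self_similar}"
        )
        for lo, hi, r in branching_ratios_adjacent(summaries[m]):
            shown = "gap" if r is None else f"{r:.2f}"
            print(f"{'':>19}R({lo}->{hi}) = {shown}")

    beta = predict_beta(fits["N"], fits["A"])
    print(
        f"predicted exponent beta = gamma/lam = {beta.beta:.3f} "
        f"(se {beta.se:.3f}): range grows as N^{beta.beta:.2f} across levels"
    )

    qdf = pd.concat(
        [quantile_horton_fit(table, m, (0.1, 0.25, 0.5, 0.75, 0.9)) for m in "NAD"],
        ignore_index=True,
    )
    write_report(qdf, args.outdir / "quantile_slopes.csv")
    spread = qdf.groupby("metric")["slope"].agg(["min", "max"])
    print("quantile-slope ranges (self-similarity beyond the mean):")
    print(spread.to_string())

    figdir = args.outdir / "figures"
    figdir.mkdir(exist_ok=True)
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.6), sharex=True)
    for ax, m in zip(axes, ("N", "A", "D")):
        lv = [s.level for s in summaries[m]]
        ml = [s.mean_log for s in summaries[m]]
        sd = [s.sd_log for s in summaries[m]]
        ax.errorbar(lv, ml, yerr=sd, fmt="o", capsize=3)
        fit = fits[m]
        ax.plot(lv, [fit.intercept + fit.slope * w for w in lv], "k-")
        ax.set_xlabel("hierarchy level $\\omega$")
        ax.set_ylabel(f"mean ln {m}")
        ax.set_title(f"{label[m]}: ratio {fit.branching_ratio:.2f}/level")
    fig.tight_layout()
    fig.savefig(figdir / "means_vs_level.png", dpi=120)
    print(f"wrote {figdir / 'means_vs_level.png'}")


if __name__ == "__main__":
    main()
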