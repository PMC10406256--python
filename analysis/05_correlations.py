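#!/usr/bin/env python
"""Correlate histology and dMRI regional measures; plot the linear fits.

Heterogeneity correlations (hCAD vs hFA/hTR/hMSD/hRTOP) pool all 36
(subject, region) points and are also split by region class; average
correlations run separately in cortical and subcortical regions.  p-values
get Benjamini-Hochberg correction within each family.  Scatter plots show
the regression line with a 95% confidence band and per-region colors.
"""

import argparse
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from cytodmri.correlate import linear_fit_with_band, run_study_correlations
from cytodmri.io import read_summary_table


def scatter_with_band(ax, x, y, regions, title):
    palette = plt.get_cmap("tab10")
    for i, region in enumerate(sorted(set(regions))):
        sel = regions == region
        ax.scatter(x[sel], y[sel], s=18, color=palette(i % 10), label=region)
    slope, intercept, grid, half = linear_fit_with_band(x, y)
    ax.plot(grid, intercept + slope * grid, "k-", lw=1)
    ax.fill_between(grid, intercept + slope * grid - half,
                    intercept + slope * grid + half, color="gray", alpha=0.3)
    ax.set_title(title, fontsize=9)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--summary", type=Path, default=Path("results/regional_summary.csv"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    table = read_summary_table(args.summary)
    results = run_study_correlations(table)
    args.out.mkdir(parents=True, exist_ok=True)
    results.to_csv(args.out / "correlations.csv", index=False)

    pooled = results.query("group == 'all'").set_index("pair")
    print("heterogeneity correlations over all 36 (subject, region) points:")
    for pair, row in pooled.iterrows():
        flag = "*" if row.q < 0.05 else " "
        print(f"  {pair}: r = {row.r:+.2f}, p = {row.p:.2g}, q = {row.q:.2g} {flag}")

    wide = table.pivot_table(index=["subject", "region"], columns="measure",
                             values="heterogeneity", aggfunc="first").reset_index()
    fig, axes = plt.subplots(1, 3, figsize=(11, 3.4), constrained_layout=True)
    for ax, meas in zip(axes, ("TR", "MSD", "FA")):
        row = pooled.loc[f"hCAD~h{meas}"]
        scatter_with_band(
            ax,
            wide["CAD"].to_numpy(float),
            wide[meas].to_numpy(float),
            wide["region"].to_numpy(),
            f"hCAD vs h{meas}  (r={row.r:.2f}, p={row.p:.1g})",
        )
        ax.set_xlabel("heterogeneity of cell area density")
        ax.set_ylabel(f"heterogeneity of {meas}")
    axes[-1].legend(fontsize=6, loc="best", ncols=2)
    fig.savefig(args.out / "heterogeneity_correlations.png", dpi=150)
    print(f"results written to {args.out / 'correlations.csv'} and "
          f"{args.out / 'heterogeneity_correlations.png'}")


if __name__ == "__main__":
    main()
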