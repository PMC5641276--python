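"""Linkage-disequilibrium experiments.

Writes:
  ld_decay.json          decay fit + 0.2-threshold distance within one landrace
  ld_grid.tsv            mean decay distance over the g x l sampling grid
  ld_sample_size.tsv     decay mean/variance at varying within-landrace sizes
  ld_interchrom.*.tsv    MAF-matched interchromosomal LD fractions + Wilcoxon
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from landracekit import (
    decay_distance,
    hill_weir_fit,
    interchromosomal_comparison,
    pairwise_ld,
    read_panel,
    sample_size_ld,
    sampling_scheme_ld,
)
from landracekit.pipeline import child_seed

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--panels", type=Path, default=ROOT / "results" / "panels")
    ap.add_argument("--outdir", type=Path, default=ROOT / "results")
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    landrace = read_panel(args.panels / "landrace.vcf", args.panels / "landrace.popmap.tsv")
    design = read_panel(args.panels / "design.vcf", args.panels / "design.popmap.tsv")

    # decay within the deep-LD landrace (all 48 individuals)
    table = pairwise_ld(landrace.to_haplotype_set())
    fit = hill_weir_fit(table, n_gametes=2 * landrace.n_individuals)
    dd = decay_distance(fit, threshold=0.2)
    payload = dict(rho_per_bp=fit.rho_per_bp, n_gametes=fit.n_gametes,
                   n_pairs=fit.n_pairs, mean_r2=float(table["r2"].mean()),
                   decay_distance_kb=dd.distance_bp / 1000 if dd.reached else None,
                   status=dd.status)
    with open(args.outdir / "ld_decay.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    print(f"within-landrace decay distance: {dd.distance_bp / 1000:.1f} kb ({dd.status})")

    # g x l sampling grid at informative cells
    grid = sampling_scheme_ld(
        design, l_values=[1, 2, 5, 10], g_values=[4, 8, 20, 40], repeats=10,
        seed=child_seed(args.seed, "grid"),
    )
    gdf = pd.DataFrame(grid.mean_decay_bp / 1000, index=grid.g_values, columns=grid.l_values)
    gdf.index.name = "g_per_landrace"
    gdf.columns.name = "l_landraces"
    gdf.to_csv(args.outdir / "ld_grid.tsv", sep="\t")
    print("grid of mean decay distances (kb):")
    print(gdf.to_string(float_format=lambda v: f"{v:.2f}"))

    # within-landrace sample-size experiment
    ss = sample_size_ld(landrace, "P1", sizes=[5, 10, 20, 45], repeats=10,
                        seed=child_seed(args.seed, "sample_size"))
    ss.to_csv(args.outdir / "ld_sample_size.tsv", sep="\t", index=False)
    print(ss.to_string(index=False))

    # MAF-matched interchromosomal LD vs landrace composition
    frac, tests = interchromosomal_comparison(
        design, l_values=[1, 2, 4, 8], repeats=10, seed=child_seed(args.seed, "interchrom"),
        n_individuals=24, maf_bin_width=0.1, snps_per_bin_per_chrom=15,
    )
    frac.to_csv(args.outdir / "ld_interchrom.fractions.tsv", sep="\t", index=False)
    tests.to_csv(args.outdir / "ld_interchrom.tests.tsv", sep="\t", index=False)
    means = frac.groupby("l")["fraction_r2_gt_threshold"].mean()
    print("interchromosomal fraction r2 > 0.2 by composition:")
    print(means.to_string(float_format=lambda v: f"{v:.4f}"))


if __name__ == "__main__":
    main()
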