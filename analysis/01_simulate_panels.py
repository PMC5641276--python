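"""Simulate the three study panels and write them as VCF + popmap + truth.

Panels:
  design    10 landraces x 24 individuals, drift calibrated so that the
            expected fixation index is ~0.27 (~2000 polymorphic SNPs)
  landrace  a single deep-LD landrace of 48 individuals
  pair      two landraces that split from a shared LD-carrying ancestor

Outputs go to results/panels/.  Rerun with the same seed to regenerate
bit-identical files.
"""

import argparse
import json
from pathlib import Path

from landracekit import (
    SimulationConfig,
    phase_pair_config,
    simulate_panel,
    single_landrace_config,
    write_panel,
)
from landracekit.pipeline import child_seed

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=ROOT / "results" / "panels")
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    configs = {
        "design": SimulationConfig(
            n_snps_per_chrom=450, seed=child_seed(args.seed, "design")
        ),
        "landrace": single_landrace_config(seed=child_seed(args.seed, "landrace")),
        "pair": phase_pair_config(seed=child_seed(args.seed, "pair")),
    }
    for name, cfg in configs.items():
        panel, truth = simulate_panel(cfg)
        write_panel(panel, args.outdir / f"{name}.vcf", args.outdir / f"{name}.popmap.tsv")
        with open(args.outdir / f"{name}.truth.json", "w") as fh:
            json.dump(truth.to_dict(), fh, indent=2, sort_keys=True)
        print(
            f"{name}: {panel.n_individuals} individuals, {panel.n_markers} SNPs, "
            f"expected F = {truth.expected_fst:.4f}"
        )


if __name__ == "__main__":
    main()
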