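"""Per-landrace diversity table: PP, pi, window H, F_is with permutation p.

Reads the design panel written by 01_simulate_panels.py and writes one row
per landrace, mirroring a per-population diversity summary table.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from landracekit import WindowSpec, diversity_summary, read_panel
from landracekit.pipeline import child_seed

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--panels", type=Path, default=ROOT / "results" / "panels")
    ap.add_argument("--outdir", type=Path, default=ROOT / "results")
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    panel = read_panel(args.panels / "design.vcf", args.panels / "design.popmap.tsv")
    rng = np.random.default_rng(child_seed(args.seed, "diversity"))
    rows = []
    for pop in panel.population_labels:
        sub = panel.take_samples(panel.individuals_of(pop))
        s = diversity_summary(sub, WindowSpec(), n_perms=500, seed=rng.integers(2**31))
        rows.append(
            dict(landrace=pop, n=sub.n_individuals, PP=s.PP, pi=s.pi_mean,
                 H=s.H_mean, n_windows=s.n_windows, Fis=s.Fis, Fis_p=s.Fis_p)
        )
    df = pd.DataFrame(rows)
    out = args.outdir / "diversity.tsv"
    df.to_csv(out, sep="\t", index=False)
    print(df.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
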