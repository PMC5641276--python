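"""Population structure and variance decomposition on the design panel.

Writes: modified Rogers' distance matrix, neighbor-joining tree, principal
coordinates, AMOVA (gametic units, permutation test), the variance-captured
curve for groups of l landraces, and a Mantel + Procrustes comparison of
the full marker set against an LD-pruned subset (a marker-overlap-style
robustness check).
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from landracekit import (
    ld_prune,
    mantel,
    mrd,
    neighbor_joining,
    pcoa,
    procrustes_fit,
    read_panel,
    variance_captured,
)
from landracekit.amova import amova_gametic
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

    # distances, tree, ordination
    dm = mrd(panel)
    dm.to_frame().to_csv(args.outdir / "mrd.tsv", sep="\t")
    (args.outdir / "njt.nwk").write_text(neighbor_joining(dm) + "\n")
    coords = pcoa(dm, k=3)
    pd.DataFrame(coords.axes, index=coords.labels,
                 columns=["PCo1", "PCo2", "PCo3"]).to_csv(args.outdir / "pcoa.tsv", sep="\t")

    # AMOVA with gametes as the molecular units
    res = amova_gametic(panel, n_perms=999, seed=child_seed(args.seed, "amova"))
    with open(args.outdir / "amova.json", "w") as fh:
        json.dump(res.__dict__, fh, indent=2, sort_keys=True)
    print(f"AMOVA: {res.pct_among:.1f}% among / {res.pct_within:.1f}% within, "
          f"Phi_ST = {res.phi_st:.3f}, p = {res.p_value:.4f}")

    # variance captured by random groups of l landraces
    ls = [1, 2, 5]
    curve = variance_captured(dm.values, panel.populations, ls,
                              n_repeats=400, seed=child_seed(args.seed, "capture"))
    rows = [
        dict(l=l, mean=v.mean(), q25=np.quantile(v, 0.25), median=np.median(v),
             q75=np.quantile(v, 0.75), n=v.size)
        for l, v in ((l, curve.distributions[l]) for l in ls)
    ]
    pd.DataFrame(rows).to_csv(args.outdir / "capture_curve.tsv", sep="\t", index=False)
    for row in rows:
        print(f"l={row['l']}: mean captured {row['mean']:.3f}")

    # robustness: does an LD-pruned marker subset give the same structure?
    pruned = ld_prune(panel.to_haplotype_set())
    keep_ids = set(pruned.markers["id"])
    sub = panel.take_markers(
        np.flatnonzero(panel.markers["id"].isin(keep_ids).to_numpy())
    )
    dm_sub = mrd(sub)
    r, p = mantel(dm, dm_sub, n_perms=999, seed=child_seed(args.seed, "mantel"))
    fit = procrustes_fit(coords, pcoa(dm_sub, k=3), k=3)
    with open(args.outdir / "marker_subset_agreement.json", "w") as fh:
        json.dump({"n_markers_full": panel.n_markers, "n_markers_pruned": sub.n_markers,
                   "mantel_r": r, "mantel_p": p, "procrustes_fit": fit},
                  fh, indent=2, sort_keys=True)
    print(f"pruned subset: {sub.n_markers}/{panel.n_markers} markers, "
          f"Mantel r = {r:.3f} (p = {p:.4f}), Procrustes fit = {fit:.3f}")


if __name__ == "__main__":
    main()
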