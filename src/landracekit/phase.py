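"""Persistence of linkage phase between populations.

For marker pairs polymorphic in both populations and within 1 Mb, the
signed gametic correlations ``r`` are compared between the two populations:
per 10-kb physical-distance bin, the Pearson correlation of the paired
``r`` values and the proportion of pairs with equal sign of ``r`` (PEP).
Pairs with ``r = 0`` in either population are excluded from PEP (their sign
is undefined); the excluded count is reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ld import r_matrix
from .panel import HaplotypeSet, PanelError, PopulationPanel

PHASE_COLUMNS = ["bin_start", "bin_end", "corr_r", "pep", "n_pairs", "n_zero_excluded"]


@dataclass
class PhasePersistence:
    """Per-bin phase-persistence summary between two gamete sets."""

    bin_bp: int
    table: pd.DataFrame           # columns PHASE_COLUMNS; NaN where undefined
    corr_r_pooled: float          # correlation over all pairs <= max distance
    pep_pooled: float
    n_pairs_total: int

    def corr_in_bin(self, k: int) -> float:
        return float(self.table["corr_r"].iloc[k])

    def pep_in_bin(self, k: int) -> float:
        return float(self.table["pep"].iloc[k])


def _check_same_markers(a: HaplotypeSet, b: HaplotypeSet) -> None:
    cols = ["chrom", "pos", "ref", "alt"]
    if len(a.markers) != len(b.markers) or not a.markers[cols].equals(b.markers[cols]):
        raise PanelError("haplotype sets must share an identical, identically oriented marker list")


def phase_persistence(
    haps_a: HaplotypeSet,
    haps_b: HaplotypeSet,
    max_dist_bp: int = 1_000_000,
    bin_bp: int = 10_000,
) -> PhasePersistence:
    """Compare signed r between two populations across distance bins.

    Bins are half-open ``(k*bin_bp, (k+1)*bin_bp]``.  Pairs enter only when
    both markers are polymorphic (r defined) in BOTH populations.
    """
    _check_same_markers(haps_a, haps_b)
    markers = haps_a.markers
    ra_all, rb_all, dist_all = [], [], []
    for chrom in markers["chrom"].unique():
        cidx = np.flatnonzero((markers["chrom"] == chrom).to_numpy())
        if cidx.size < 2:
            continue
        pos = markers["pos"].to_numpy()[cidx]
        ra, _ = r_matrix(haps_a.haplotypes[:, cidx])
        rb, _ = r_matrix(haps_b.haplotypes[:, cidx])
        iu, ju = np.triu_indices(cidx.size, k=1)
        dist = pos[ju] - pos[iu]
        ok = (dist <= max_dist_bp) & np.isfinite(ra[iu, ju]) & np.isfinite(rb[iu, ju])
        ra_all.append(ra[iu, ju][ok])
        rb_all.append(rb[iu, ju][ok])
        dist_all.append(dist[ok])
    if not dist_all or sum(d.size for d in dist_all) == 0:
        raise PanelError("no shared polymorphic marker pairs within the distance limit")
    ra = np.concatenate(ra_all)
    rb = np.concatenate(rb_all)
    dist = np.concatenate(dist_all)

    n_bins = int(np.ceil(max_dist_bp / bin_bp))
    # (0, bin] half-open on the left: distance d falls in bin ceil(d/bin)-1
    bins = np.ceil(dist / bin_bp).astype(int) - 1
    rows = []
    for k in range(n_bins):
        sel = bins == k
        n_pairs = int(sel.sum())
        corr = np.nan
        pep = np.nan
        n_zero = 0
        if n_pairs >= 2:
            xa, xb = ra[sel], rb[sel]
            if xa.std() > 0 and xb.std() > 0:
                corr = float(np.corrcoef(xa, xb)[0, 1])
            prod = xa * xb
            nz = prod != 0
            n_zero = int((~nz).sum())
            if nz.any():
                pep = float((prod[nz] > 0).mean())
        rows.append((k * bin_bp, (k + 1) * bin_bp, corr, pep, n_pairs, n_zero))
    table = pd.DataFrame(rows, columns=PHASE_COLUMNS)

    corr_pooled = float(np.corrcoef(ra, rb)[0, 1]) if ra.std() > 0 and rb.std() > 0 else np.nan
    prod = ra * rb
    nz = prod != 0
    pep_pooled = float((prod[nz] > 0).mean()) if nz.any() else np.nan
    return PhasePersistence(
        bin_bp=bin_bp,
        table=table,
        corr_r_pooled=corr_pooled,
        pep_pooled=pep_pooled,
        n_pairs_total=int(dist.size),
    )


@dataclass
class SplitHalfResult:
    """Aggregated split-half persistence over repeats."""

    bin_bp: int
    mean_table: pd.DataFrame      # per-bin means of corr_r and pep over repeats
    pooled_corr_r: np.ndarray     # per-repeat pooled summaries
    pooled_pep: np.ndarray
    repeats: int


def split_half_persistence(
    panel: PopulationPanel,
    population: str,
    repeats: int = 100,
    seed: int | np.random.Generator = 0,
    max_dist_bp: int = 1_000_000,
    bin_bp: int = 10_000,
) -> SplitHalfResult:
    """Within-population control: individuals split into random halves and
    the halves compared with :func:`phase_persistence`, ``repeats`` times."""
    idx = panel.individuals_of(population)
    if idx.size < 8:
        raise PanelError(f"population {population!r} needs >= 8 individuals for split halves")
    rng = np.random.default_rng(seed)
    n_bins = int(np.ceil(max_dist_bp / bin_bp))
    corr_acc = np.full((repeats, n_bins), np.nan)
    pep_acc = np.full((repeats, n_bins), np.nan)
    pooled_corr = np.empty(repeats)
    pooled_pep = np.empty(repeats)
    half = idx.size // 2
    for rep in range(repeats):
        perm = rng.permutation(idx)
        a = panel.take_samples(np.sort(perm[:half]))
        b = panel.take_samples(np.sort(perm[half:]))
        pp = phase_persistence(a.to_haplotype_set(), b.to_haplotype_set(), max_dist_bp, bin_bp)
        corr_acc[rep] = pp.table["corr_r"].to_numpy()
        pep_acc[rep] = pp.table["pep"].to_numpy()
        pooled_corr[rep] = pp.corr_r_pooled
        pooled_pep[rep] = pp.pep_pooled
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins -> NaN
        mean_table = pd.DataFrame(
            {
                "bin_start": np.arange(n_bins) * bin_bp,
                "bin_end": (np.arange(n_bins) + 1) * bin_bp,
                "corr_r": np.nanmean(corr_acc, axis=0),
                "pep": np.nanmean(pep_acc, axis=0),
                "n_repeats_defined": np.isfinite(corr_acc).sum(axis=0),
            }
        )
    return SplitHalfResult(
        bin_bp=bin_bp,
        mean_table=mean_table,
        pooled_corr_r=pooled_corr,
        pooled_pep=pooled_pep,
        repeats=repeats,
    )
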