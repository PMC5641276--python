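"""Genetic diversity statistics: PP, per-marker pi, window haplotype
heterozygosity, and Weir-Cockerham F_is with a permutation test.

All estimators use unbiased small-sample corrections (``k/(k-1)``), as in
the classical formulations of per-marker nucleotide diversity and haplotype
heterozygosity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .panel import MISSING, HaplotypeSet, PanelError, PopulationPanel

logger = logging.getLogger(__name__)


@dataclass
class WindowSpec:
    """Sliding-window definition for haplotype heterozygosity.

    One window is anchored at each SNP, spanning ``[pos, pos + width_bp)``;
    windows with fewer than ``min_snps`` SNPs are skipped.
    """

    width_bp: int = 100_000
    min_snps: int = 5

    def __post_init__(self) -> None:
        if self.width_bp <= 0:
            raise ValueError("width_bp must be positive")
        if self.min_snps < 2:
            raise ValueError("min_snps must be >= 2")


@dataclass
class DiversitySummary:
    """Per-population (or per-sample) diversity summary."""

    PP: float
    pi_mean: float
    H_mean: float | None
    n_windows: int
    Fis: float | None
    Fis_p: float | None


def proportion_polymorphic(panel: PopulationPanel) -> float:
    """Fraction of markers with both alleles observed among non-missing calls."""
    if panel.n_markers == 0:
        raise PanelError("empty panel")
    g = panel.genotypes
    called = g != MISSING
    has_alt = ((g > 0) & called).any(axis=0)
    has_ref = ((g < 2) & called).any(axis=0)
    return float((has_alt & has_ref).mean())


def nucleotide_diversity(panel: PopulationPanel) -> tuple[np.ndarray, float]:
    """Per-marker nucleotide diversity and its mean.

    For a marker with ``k`` callable gametes and alt-allele frequency ``p``,
    ``pi = (k/(k-1)) * 2 p (1-p)`` — the unbiased probability that two random
    gametes differ.  Markers with fewer than 2 callable gametes are excluded
    from the mean (and reported as NaN); monomorphic markers contribute 0.
    """
    g = panel.genotypes
    called = g != MISSING
    k = 2 * called.sum(axis=0).astype(float)
    alt = np.where(called, g, 0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(k > 0, alt / k, np.nan)
        pi = np.where(k >= 2, (k / np.maximum(k - 1, 1)) * 2 * p * (1 - p), np.nan)
    n_excluded = int((k < 2).sum())
    if n_excluded:
        logger.info("nucleotide_diversity excluded %d markers with <2 callable gametes", n_excluded)
    valid = ~np.isnan(pi)
    if not valid.any():
        raise PanelError("no marker with >= 2 callable gametes")
    return pi, float(pi[valid].mean())


def haplotype_heterozygosity(
    haps: HaplotypeSet, spec: WindowSpec | None = None
) -> tuple[np.ndarray, float]:
    """Sliding-window haplotype heterozygosity and its mean over windows.

    Within each window the haplotype classes are the distinct allele strings
    over the window's SNPs among gametes with complete calls; with ``k``
    complete gametes and class frequencies ``x_c``,
    ``H = (k/(k-1)) (1 - sum x_c^2)``.
    """
    spec = spec or WindowSpec()
    values: list[float] = []
    markers = haps.markers
    H = haps.haplotypes
    for chrom in markers["chrom"].unique():
        cidx = np.flatnonzero((markers["chrom"] == chrom).to_numpy())
        pos = markers["pos"].to_numpy()[cidx]
        sub = H[:, cidx]
        ends = np.searchsorted(pos, pos + spec.width_bp, side="left")
        for s, e in enumerate(ends):
            if e - s < spec.min_snps:
                continue
            block = sub[:, s:e]
            complete = (block != MISSING).all(axis=1)
            k = int(complete.sum())
            if k < 2:
                continue
            _, counts = np.unique(block[complete], axis=0, return_counts=True)
            x = counts / k
            values.append((k / (k - 1)) * (1.0 - float((x**2).sum())))
    if not values:
        raise PanelError("no window satisfied the minimum SNP count")
    arr = np.array(values)
    return arr, float(arr.mean())


# ---------------------------------------------------------------------------
# Weir-Cockerham F_is (single population) with permutation test
# ---------------------------------------------------------------------------

def _wc_components(n: np.ndarray, p: np.ndarray, h: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Weir-Cockerham (1984) single-population variance components per locus.

    ``n``: called individuals, ``p``: alt frequency, ``h``: observed
    heterozygote frequency.  Returns (b, c); the multi-locus inbreeding
    estimate is ``f = 1 - sum(c) / sum(b + c)``.
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        b = (n / (n - 1)) * (p * (1 - p) - (2 * n - 1) / (4 * n) * h)
    c = h / 2.0
    return b, c


def _fis_from_counts(n: np.ndarray, p: np.ndarray, h: np.ndarray) -> float:
    b, c = _wc_components(n, p, h)
    denom = (b + c).sum()
    if denom == 0:
        raise PanelError("F_is undefined: all loci monomorphic")
    return float(1.0 - c.sum() / denom)


def fis(
    panel: PopulationPanel, n_perms: int = 1000, seed: int | np.random.Generator = 0
) -> tuple[float, float]:
    """Multi-locus Weir-Cockerham F_is for one population, with permutation p.

    The null re-pairs the called alleles at each locus into genotypes
    uniformly at random (Hardy-Weinberg null) and recomputes ``f``; the
    two-sided p-value uses +1 smoothing.  Callers analysing a multi-landrace
    panel loop over populations.
    """
    if n_perms < 1:
        raise ValueError("n_perms must be >= 1")
    rng = np.random.default_rng(seed)
    g = panel.genotypes
    called = g != MISSING
    n = called.sum(axis=0).astype(float)
    ok = n >= 2
    g = g[:, ok]
    called = called[:, ok]
    n = n[ok]
    alt = np.where(called, g, 0).sum(axis=0).astype(float)
    p = alt / (2 * n)
    het = (np.where(called, g, -9) == 1).sum(axis=0) / n
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise PanelError("F_is undefined: all loci monomorphic")
    f_obs = _fis_from_counts(n[poly], p[poly], het[poly])

    # permutation: random pairing of the 2n alleles per locus;
    # heterozygote count from a uniformly random pairing of a alt and 2n-a ref
    idx = np.flatnonzero(poly)
    n_i = n[idx].astype(int)
    a_i = alt[idx].astype(int)
    # random pairing realized by shuffling the allele vector and pairing
    # consecutive entries; all permutations of one locus drawn at once
    het_freq = np.empty((n_perms, idx.size))
    for j in range(idx.size):
        alleles = np.zeros(2 * n_i[j], dtype=np.int8)
        alleles[: a_i[j]] = 1
        block = rng.permuted(np.tile(alleles, (n_perms, 1)), axis=1)
        pairs = block.reshape(n_perms, n_i[j], 2)
        het_freq[:, j] = (pairs[:, :, 0] != pairs[:, :, 1]).sum(axis=1) / n_i[j]
    f_perm = np.array(
        [_fis_from_counts(n[idx], p[idx], het_freq[perm]) for perm in range(n_perms)]
    )
    ge = int((f_perm >= f_obs).sum())
    le = int((f_perm <= f_obs).sum())
    p_val = min(1.0, 2.0 * min((ge + 1) / (n_perms + 1), (le + 1) / (n_perms + 1)))
    return f_obs, p_val


def diversity_summary(
    panel: PopulationPanel,
    window: WindowSpec | None = None,
    n_perms: int = 1000,
    seed: int | np.random.Generator = 0,
    with_fis: bool = True,
) -> DiversitySummary:
    """PP, mean pi, mean window H and F_is for a (single-population) panel."""
    pp = proportion_polymorphic(panel)
    _, pi_mean = nucleotide_diversity(panel)
    H_mean = None
    n_windows = 0
    if panel.phased:
        try:
            hvals, H_mean = haplotype_heterozygosity(panel.to_haplotype_set(), window)
            n_windows = len(hvals)
        except PanelError:
            H_mean = None
    f = p = None
    if with_fis:
        try:
            f, p = fis(panel, n_perms=n_perms, seed=seed)
        except PanelError:
            f = p = None
    return DiversitySummary(PP=pp, pi_mean=pi_mean, H_mean=H_mean, n_windows=n_windows, Fis=f, Fis_p=p)
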