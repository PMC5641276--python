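"""Folded site-frequency spectra by repeated gamete subsampling.

For each SNP, ``g`` gametes are drawn without replacement from the gametes
with non-missing calls and the minor-allele count inside the drawn sample is
recorded; class masses are accumulated over SNPs and resampling repeats.
``g = floor(2 n c)`` couples the gamete sample size to the panel's minimum
call rate ``c``.  The neutral reference spectrum follows the standard
coalescent expectation ``E[f_i] proportional to 1/i``, folded onto
minor-allele classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .panel import MISSING, PanelError, PopulationPanel


@dataclass
class FoldedSFS:
    """Folded spectrum over minor-allele-count classes 1 .. floor(g/2).

    ``proportions[i-1]`` is the mass of class ``i``; ``monomorphic_mass`` is
    the mass of draws in which the sampled gametes were monomorphic.  The
    class masses plus the monomorphic mass sum to 1.
    """

    g: int
    proportions: np.ndarray
    monomorphic_mass: float = 0.0
    n_reps: int = 0
    n_snps: int = 0

    @property
    def n_classes(self) -> int:
        return self.g // 2

    def mean_maf(self) -> float:
        """Mean minor-allele frequency over polymorphic class mass."""
        classes = np.arange(1, self.n_classes + 1) / self.g
        total = self.proportions.sum()
        if total == 0:
            return 0.0
        return float((classes * self.proportions).sum() / total)

    def total_variation(self, other: "FoldedSFS") -> float:
        """Total-variation distance between the polymorphic-class distributions."""
        if self.g != other.g:
            raise ValueError("spectra have different gamete counts")
        p = self.proportions / self.proportions.sum()
        q = other.proportions / other.proportions.sum()
        return float(0.5 * np.abs(p - q).sum())


def expected_neutral_sfs(g: int) -> FoldedSFS:
    """Expected folded SFS for ``g`` gametes under neutral coalescent theory.

    The unfolded expectation is ``E[f_i] = (1/i) / sum_{j<g} 1/j``; folding
    adds classes ``i`` and ``g - i`` for ``i < g/2`` and keeps ``i = g/2``.
    """
    if g < 2:
        raise ValueError("need at least 2 gametes")
    i = np.arange(1, g)
    unfolded = (1.0 / i) / (1.0 / i).sum()
    half = g // 2
    folded = np.empty(half)
    for k in range(1, half + 1):
        if k < g - k:
            folded[k - 1] = unfolded[k - 1] + unfolded[g - k - 1]
        else:  # k == g/2 for even g
            folded[k - 1] = unfolded[k - 1]
    return FoldedSFS(g=g, proportions=folded, monomorphic_mass=0.0)


def folded_sfs(
    panel: PopulationPanel,
    call_rate_c: float = 0.9,
    n_reps: int = 1000,
    seed: int | np.random.Generator = 0,
    method: str = "mass",
) -> FoldedSFS:
    """Folded SFS of a panel by repeated without-replacement gamete sampling.

    Parameters
    ----------
    call_rate_c : minimum call rate; the per-SNP gamete sample size is
        ``g = floor(2 * n_individuals * call_rate_c)``.
    n_reps : resampling repeats per SNP.
    method : ``"mass"`` accumulates one class observation per SNP and repeat
        (default); ``"rounded"`` averages each SNP's minor-allele count over
        repeats, rounds to the nearest class, and bins once per SNP.

    Notes
    -----
    Drawing ``g`` gametes without replacement and counting alt alleles is a
    hypergeometric draw; it is implemented as such, vectorized over SNPs and
    repeats.  SNP/repeat combinations with fewer than ``g`` callable gametes
    are skipped.
    """
    if panel.n_markers == 0:
        raise PanelError("empty panel")
    if method not in {"mass", "rounded"}:
        raise ValueError("method must be 'mass' or 'rounded'")
    rng = np.random.default_rng(seed)
    n = panel.n_individuals
    g = int(np.floor(2 * n * call_rate_c))
    if g < 2:
        raise PanelError(f"g = floor(2*{n}*{call_rate_c}) = {g} < 2")

    geno = panel.genotypes
    called = geno != MISSING
    k = 2 * called.sum(axis=0)          # callable gametes per SNP
    a = np.where(called, geno, 0).sum(axis=0)  # alt gametes per SNP
    usable = k >= g
    if not usable.any():
        raise PanelError(f"no SNP has {g} callable gametes")
    k_u = k[usable]
    a_u = a[usable]
    n_snps = int(usable.sum())

    half = g // 2
    counts = np.zeros(half + 1, dtype=np.int64)  # index 0 = monomorphic draws
    if method == "mass":
        for _ in range(n_reps):
            alt = rng.hypergeometric(a_u, k_u - a_u, g)
            minor = np.minimum(alt, g - alt)
            counts += np.bincount(minor, minlength=half + 1)
        total = n_snps * n_reps
    else:
        mean_minor = np.zeros(n_snps)
        for _ in range(n_reps):
            alt = rng.hypergeometric(a_u, k_u - a_u, g)
            mean_minor += np.minimum(alt, g - alt)
        mean_minor /= n_reps
        binned = np.rint(mean_minor).astype(np.int64)
        counts += np.bincount(binned, minlength=half + 1)
        total = n_snps

    proportions = counts[1:] / total
    return FoldedSFS(
        g=g,
        proportions=proportions,
        monomorphic_mass=counts[0] / total,
        n_reps=n_reps,
        n_snps=n_snps,
    )
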