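"""Distance-based analysis of molecular variance (one level: within vs among
populations) and the variance-captured-by-groups resampling experiment.

The decomposition follows the classical squared-distance formulation: with
``N`` individuals in ``P`` populations and squared pairwise distances
``d2``, the total sum of squares is ``SS_total = (1/N) sum_{i<j} d2_ij`` and
the within component sums the analogous per-population terms.  The
differentiation statistic ``Phi_ST`` is the among-population share of the
variance components, with significance from label permutations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .panel import PanelError, PopulationPanel


@dataclass
class AmovaResult:
    ss_among: float
    ss_within: float
    df_among: int
    df_within: int
    sigma2_among: float
    sigma2_within: float
    pct_among: float
    pct_within: float
    phi_st: float
    p_value: float | None
    phi_st_raw: float = 0.0  # before clamping negative among-components


@dataclass
class CaptureCurve:
    """Distributions of the proportion of total molecular variance captured
    by random groups of ``l`` populations, per ``l``."""

    l_values: list[int]
    distributions: dict[int, np.ndarray]
    n_repeats: int

    def means(self) -> dict[int, float]:
        return {l: float(v.mean()) for l, v in self.distributions.items()}


def _within_ss(d2: np.ndarray, labels: np.ndarray, pops: np.ndarray) -> float:
    ss = 0.0
    for p in pops:
        idx = np.flatnonzero(labels == p)
        sub = d2[np.ix_(idx, idx)]
        ss += sub.sum() / (2.0 * idx.size)
    return ss


def amova(
    dist: np.ndarray,
    labels: np.ndarray | list,
    n_perms: int = 1000,
    seed: int | np.random.Generator = 0,
    permutation_blocks: np.ndarray | None = None,
) -> AmovaResult:
    """One-level AMOVA on a square distance matrix.

    Parameters
    ----------
    dist : (N, N) symmetric distance matrix (distances, not squared).
    labels : population label per unit (individual or gamete).
    n_perms : permutations for the p-value; 0 skips the test.
    permutation_blocks : optional block id per unit; units sharing a block
        (e.g. the two gametes of one individual) move together when labels
        are permuted.  Default: each unit is its own block.

    The p-value is the +1-smoothed fraction of label permutations whose
    (unclamped) Phi statistic is >= the observed one.
    """
    dist = np.asarray(dist, dtype=float)
    labels = np.asarray(labels, dtype=object)
    n = dist.shape[0]
    if dist.shape != (n, n) or len(labels) != n:
        raise PanelError("distance matrix and labels are inconsistent")
    pops, counts = np.unique(labels, return_counts=True)
    if len(pops) < 2:
        raise PanelError("AMOVA needs at least 2 populations")
    if (counts < 2).any():
        bad = pops[counts < 2][0]
        raise PanelError(f"population {bad!r} has fewer than 2 individuals")

    d2 = dist**2

    def decompose(lbl: np.ndarray) -> tuple[float, float, float, float]:
        ss_total = d2.sum() / (2.0 * n)
        ss_within = _within_ss(d2, lbl, pops)
        ss_among = ss_total - ss_within
        df_among = len(pops) - 1
        df_within = n - len(pops)
        sigma_w = ss_within / df_within
        sizes = np.array([np.count_nonzero(lbl == p) for p in pops], dtype=float)
        n0 = (n - (sizes**2).sum() / n) / df_among
        sigma_a = (ss_among / df_among - sigma_w) / n0
        return ss_among, ss_within, sigma_a, sigma_w

    ss_among, ss_within, sigma_a_raw, sigma_w = decompose(labels)
    phi_raw = sigma_a_raw / (sigma_a_raw + sigma_w)
    sigma_a = max(sigma_a_raw, 0.0)
    total = sigma_a + sigma_w
    phi = sigma_a / total if total > 0 else 0.0

    p_value = None
    if n_perms > 0:
        rng = np.random.default_rng(seed)
        if permutation_blocks is None:
            blocks = np.arange(n)
        else:
            blocks = np.asarray(permutation_blocks)
        uniq, inv = np.unique(blocks, return_inverse=True)
        # one label per block (units of a block share the population)
        block_labels = np.empty(len(uniq), dtype=object)
        block_labels[inv] = labels
        ge = 0
        for _ in range(n_perms):
            perm = rng.permutation(block_labels)[inv]
            _, _, sa, sw = decompose(perm)
            if sa / (sa + sw) >= phi_raw:
                ge += 1
        p_value = (ge + 1) / (n_perms + 1)

    return AmovaResult(
        ss_among=ss_among,
        ss_within=ss_within,
        df_among=len(pops) - 1,
        df_within=n - len(pops),
        sigma2_among=sigma_a,
        sigma2_within=sigma_w,
        pct_among=100.0 * sigma_a / total if total > 0 else 0.0,
        pct_within=100.0 * sigma_w / total if total > 0 else 100.0,
        phi_st=phi,
        p_value=p_value,
        phi_st_raw=phi_raw,
    )


def gamete_distance_matrix(panel: PopulationPanel) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Modified Rogers' distances between gametes of a phased panel.

    For gametes (haplotypes) the within-unit allele frequencies are 0/1 and
    the distance reduces to the square root of the fraction of differing
    alleles over markers called in both gametes.  Returns
    ``(dist, labels, blocks)`` where ``blocks`` ties the two gametes of an
    individual together for permutation tests.
    """
    haps = panel.to_haplotype_set()
    H = haps.haplotypes
    M = (H != -1).astype(np.float64)
    X = np.where(H == -1, 0.0, H.astype(np.float64))
    P = X * M
    shared = M @ M.T
    if (shared[~np.eye(len(M), dtype=bool)] == 0).any():
        raise PanelError("a gamete pair shares no called markers")
    diff = (P**2) @ M.T + M @ (P**2).T - 2.0 * P @ P.T
    with np.errstate(invalid="ignore"):
        d = np.sqrt(np.maximum(diff, 0.0) / shared)
    np.fill_diagonal(d, 0.0)
    d = 0.5 * (d + d.T)
    labels = haps.populations
    blocks = np.repeat(np.arange(panel.n_individuals), 2)
    return d, labels, blocks


def amova_gametic(
    panel: PopulationPanel,
    n_perms: int = 1000,
    seed: int | np.random.Generator = 0,
) -> AmovaResult:
    """AMOVA with gametes as units, so Phi_ST estimates the gametic fixation
    index (the drift F).  An individual-level decomposition collapses the
    within-individual variance and inflates Phi to ~2F/(1+F) under
    Hardy-Weinberg proportions; treating phased gametes as the molecular
    units restores the haplotypic definition.  Permutations move whole
    individuals between populations.
    """
    d, labels, blocks = gamete_distance_matrix(panel)
    return amova(d, labels, n_perms=n_perms, seed=seed, permutation_blocks=blocks)


def _total_msd(d2: np.ndarray, idx: np.ndarray) -> float:
    """Mean squared deviation: AMOVA total SS over df_total for a subset."""
    m = idx.size
    sub = d2[np.ix_(idx, idx)]
    return sub.sum() / (2.0 * m) / (m - 1)


def variance_captured(
    dist: np.ndarray,
    labels: np.ndarray | list,
    l_values: list[int],
    n_repeats: int = 1000,
    seed: int | np.random.Generator = 0,
) -> CaptureCurve:
    """Proportion of the panel's total molecular variance captured by random
    groups of ``l`` populations.

    Per repeat, the ``P`` populations are randomly partitioned into
    ``ceil(P/l)`` groups (the last group takes the remainder when ``P`` is
    not a multiple of ``l``).  Each group contributes one captured
    proportion: the group's AMOVA mean squared deviation
    (``SS_total/df_total`` over the group's individuals) divided by the full
    panel's.  Group values are pooled into the distribution for that ``l``.
    """
    dist = np.asarray(dist, dtype=float)
    labels = np.asarray(labels, dtype=object)
    d2 = dist**2
    pops = np.unique(labels)
    P = len(pops)
    for l in l_values:
        if not 1 <= l <= P:
            raise PanelError(f"group size {l} outside [1, {P}]")
    rng = np.random.default_rng(seed)
    full = _total_msd(d2, np.arange(len(labels)))
    pop_members = {p: np.flatnonzero(labels == p) for p in pops}

    distributions: dict[int, np.ndarray] = {}
    for l in l_values:
        n_groups = int(np.ceil(P / l))
        values: list[float] = []
        for _ in range(n_repeats):
            order = rng.permutation(pops)
            for gidx in range(n_groups):
                group_pops = order[gidx * l : (gidx + 1) * l]
                idx = np.concatenate([pop_members[p] for p in group_pops])
                if idx.size < 2:
                    continue
                values.append(_total_msd(d2, idx) / full)
        distributions[l] = np.array(values)
    return CaptureCurve(l_values=list(l_values), distributions=distributions, n_repeats=n_repeats)
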