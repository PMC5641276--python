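"""Population structure: modified Rogers' distances, neighbor joining,
principal coordinate analysis, Mantel and Procrustes comparisons, and
LD pruning of markers for structure-analysis input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import procrustes as _scipy_procrustes

from .ld import r_matrix
from .panel import MISSING, HaplotypeSet, PanelError, PopulationPanel

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise PanelError("distance matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise PanelError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise PanelError("distance matrix diagonal is not zero")

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass
class Coordinates:
    """Principal coordinates: axes ordered by non-increasing eigenvalue.
    All eigenvalues of the centered matrix are reported, including negative
    ones, but only nonnegative-eigenvalue axes carry coordinates."""

    labels: list[str]
    axes: np.ndarray
    eigenvalues: np.ndarray


def mrd(panel: PopulationPanel) -> DistanceMatrix:
    """Pairwise modified Rogers' distances between individuals.

    With within-individual alt-allele frequencies ``p in {0, 1/2, 1}``
    (dosage / 2) and the ``m`` markers non-missing in both individuals,
    ``MRD = sqrt((1/(2m)) * sum_markers sum_alleles (p_x - p_y)^2)``, which
    for bi-allelic SNPs reduces to the root mean square of ``p_x - p_y``.
    Ranges from 0 (identical) to 1 (opposite homozygotes everywhere).
    """
    if panel.n_individuals < 2:
        raise PanelError("need at least 2 individuals")
    g = panel.genotypes
    M = (g != MISSING).astype(np.float64)
    X = np.where(g == MISSING, 0.0, g / 2.0)
    P = X * M
    shared = M @ M.T
    off = ~np.eye(len(M), dtype=bool)
    if (shared[off] == 0).any():
        i, j = np.argwhere((shared == 0) & off)[0]
        raise PanelError(
            f"individuals {panel.samples[i]!r} and {panel.samples[j]!r} share no called markers"
        )
    sq = (P**2) @ M.T + M @ (P**2).T - 2.0 * P @ P.T
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.sqrt(np.maximum(sq, 0.0) / shared)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels=list(panel.samples), values=0.5 * (d + d.T))


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(dist: DistanceMatrix) -> str:
    """Classical neighbor-joining agglomeration; returns a newick string.

    Ties in the Q-matrix are broken by the lowest (i, j) label-index pair so
    the output is deterministic.  Negative branch lengths are clamped to 0
    with the deficit transferred to the sibling branch.
    """
    n = dist.n
    if n < 3:
        raise PanelError("neighbor joining needs at least 3 taxa")
    if not np.isfinite(dist.values).all():
        raise PanelError("non-finite distances")
    D = dist.values.astype(float).copy()
    nodes = [str(l) for l in dist.labels]
    active = list(range(n))

    while len(active) > 2:
        m = len(active)
        sub = D[np.ix_(active, active)]
        totals = sub.sum(axis=1)
        Q = (m - 2) * sub - totals[:, None] - totals[None, :]
        np.fill_diagonal(Q, np.inf)
        # lowest-index deterministic tie-break
        flat = np.argmin(Q)
        qmin = Q.flat[flat]
        ties = np.argwhere(np.isclose(Q, qmin, rtol=0, atol=1e-12))
        ai, aj = min((min(i, j), max(i, j)) for i, j in ties)
        i_glob, j_glob = active[ai], active[aj]
        dij = sub[ai, aj]
        li = 0.5 * dij + (totals[ai] - totals[aj]) / (2 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += -li
            li = 0.0
        if lj < 0:
            li += -lj
            lj = 0.0
        new_label = f"({nodes[i_glob]}:{li:.10g},{nodes[j_glob]}:{lj:.10g})"
        # distances from the new node to the remaining taxa
        new_row = np.zeros(D.shape[0] + 1)
        for bk, k_glob in enumerate(active):
            if k_glob in (i_glob, j_glob):
                continue
            new_row[k_glob] = 0.5 * (sub[ai, bk] + sub[aj, bk] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, : len(new_row) - 1] = new_row[:-1]
        D[: len(new_row) - 1, -1] = new_row[:-1]
        nodes.append(new_label)
        active = [k for k in active if k not in (i_glob, j_glob)] + [D.shape[0] - 1]

    a, b = active
    final = max(D[a, b], 0.0)
    return f"({nodes[a]}:{final / 2:.10g},{nodes[b]}:{final / 2:.10g});"


# ---------------------------------------------------------------------------
# PCoA / Mantel / Procrustes
# ---------------------------------------------------------------------------

def pcoa(dist: DistanceMatrix, k: int | None = None) -> Coordinates:
    """Principal coordinate analysis by Gower double-centering.

    Eigendecomposition of ``-1/2 J d^2 J``; coordinates are eigenvectors
    scaled by the square root of their (nonnegative) eigenvalues.  Negative
    eigenvalues are reported but carry no axes.
    """
    n = dist.n
    if k is None:
        k = n - 1
    if k > n - 1:
        raise PanelError("k must be <= N - 1")
    d2 = dist.values**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    vals, vecs = np.linalg.eigh(0.5 * (B + B.T))
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    n_pos = min(k, int((vals > 1e-10).sum()))
    axes = vecs[:, :n_pos] * np.sqrt(vals[:n_pos])
    return Coordinates(labels=list(dist.labels), axes=axes, eigenvalues=vals)


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perms: int = 999,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Mantel test: Pearson correlation of distance upper triangles with a
    one-sided (>=) permutation p-value (+1 smoothing)."""
    if d1.labels != d2.labels:
        raise PanelError("distance matrices must share the same labels in order")
    iu = np.triu_indices(d1.n, k=1)
    x = d1.values[iu]
    y = d2.values[iu]
    if np.std(x) == 0 or np.std(y) == 0:
        raise PanelError("zero-variance distance triangle")

    def corr(yv: np.ndarray) -> float:
        return float(np.corrcoef(x, yv)[0, 1])

    r_obs = corr(y)
    rng = np.random.default_rng(seed)
    ge = 0
    for _ in range(n_perms):
        perm = rng.permutation(d2.n)
        yp = d2.values[np.ix_(perm, perm)][iu]
        if corr(yp) >= r_obs:
            ge += 1
    return r_obs, (ge + 1) / (n_perms + 1)


def procrustes_fit(c1: Coordinates, c2: Coordinates, k: int = 3) -> float:
    """Correlation-like Procrustes statistic ``sqrt(1 - ss)`` between the
    first ``k`` axes of two ordinations (reflections allowed)."""
    if c1.labels != c2.labels:
        raise PanelError("coordinate sets must share the same labels in order")
    if c1.axes.shape[1] < k or c2.axes.shape[1] < k:
        raise PanelError(f"both ordinations need at least {k} axes")
    a = c1.axes[:, :k]
    b = c2.axes[:, :k]
    if np.allclose(a.std(axis=0), 0) or np.allclose(b.std(axis=0), 0):
        raise PanelError("degenerate configuration with zero spread")
    _, _, ss = _scipy_procrustes(a, b)
    return float(np.sqrt(max(0.0, 1.0 - ss)))


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def ld_prune(
    haps: HaplotypeSet,
    window_snps: int = 50,
    step_snps: int = 5,
    r2_threshold: float = 0.8,
) -> HaplotypeSet:
    """Sliding-window LD pruning (window of SNPs, fixed step, r^2 cutoff).

    Within each window, pairs are scanned greedily in position order; when a
    pair of still-kept markers exceeds the threshold, the member with the
    lower minor-allele frequency is removed (tie: the later position).
    Removal is final across windows.  Windows run per chromosome.
    """
    markers = haps.markers
    H = haps.haplotypes
    Mc = H != MISSING
    with np.errstate(invalid="ignore"):
        p = np.where(Mc, H, 0).sum(axis=0) / Mc.sum(axis=0)
    maf = np.minimum(p, 1 - p)
    keep = np.ones(len(markers), dtype=bool)
    for chrom in markers["chrom"].unique():
        cidx = np.flatnonzero((markers["chrom"] == chrom).to_numpy())
        m = cidx.size
        start = 0
        while True:
            end = min(start + window_snps, m)
            widx = cidx[start:end]
            r, _ = r_matrix(H[:, widx])
            r2 = r**2
            for a in range(len(widx)):
                ia = widx[a]
                if not keep[ia]:
                    continue
                for b in range(a + 1, len(widx)):
                    ib = widx[b]
                    if not keep[ia]:
                        break
                    if not keep[ib]:
                        continue
                    if np.isfinite(r2[a, b]) and r2[a, b] > r2_threshold:
                        if maf[ia] < maf[ib]:
                            keep[ia] = False
                        elif maf[ib] < maf[ia]:
                            keep[ib] = False
                        else:  # tie: drop the later position
                            keep[ib] = False
            if end >= m:
                break
            start += step_snps
    n_removed = int((~keep).sum())
    logger.info("ld_prune removed %d of %d markers", n_removed, len(markers))
    return haps.take_markers(np.flatnonzero(keep))
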