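"""Linkage disequilibrium: pairwise signed r / r^2 on gametes, the
Hill-Weir drift-recombination decay fit, threshold decay distances, and the
sampling-design experiments (sample size, landrace composition,
MAF-matched interchromosomal LD).

The signed gametic correlation for a SNP pair is
``r = (p_AB - p_A p_B) / sqrt(p_A (1-p_A) p_B (1-p_B))`` over the gametes
complete at both markers, with allele orientation fixed by the alt-allele
coding.  The expected ``r^2`` under drift-recombination balance for a
population-scaled recombination parameter ``C`` and ``n`` sampled gametes is

    E[r^2] = (10 + C) / ((2 + C)(11 + C))
             * (1 + ((3 + C)(12 + 12 C + C^2)) / (n (2 + C)(11 + C)))

with ``C = rho_per_bp * d`` for physical distance ``d``; ``rho_per_bp`` is
the single fitted parameter.  Its large-``C`` asymptote is ``1/n``, so a
decay threshold at or below ``1/n`` is never reached.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .panel import MISSING, HaplotypeSet, PanelError, PopulationPanel

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Pairwise r on gamete matrices (missing-aware, vectorized)
# ---------------------------------------------------------------------------

def r_matrix(haplotypes: np.ndarray, min_gametes: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Signed correlation matrix between all marker pairs of a gamete matrix.

    Missing entries (``-1``) are excluded pairwise: each entry uses the
    gametes complete at both markers.  Returns ``(r, n_shared)``; entries are
    NaN where fewer than ``min_gametes`` gametes are shared or where either
    marker is monomorphic on the shared set.
    """
    H = haplotypes.astype(np.float64)
    M = (haplotypes != MISSING).astype(np.float64)
    P = np.where(haplotypes == MISSING, 0.0, H)
    n = M.T @ M
    a = P.T @ M      # a[i, j] = sum of allele i over gametes complete at (i, j)
    ab = P.T @ P
    with np.errstate(invalid="ignore", divide="ignore"):
        pa = a / n
        pb = pa.T
        pab = ab / n
        d = pab - pa * pb
        denom = np.sqrt(pa * (1 - pa) * pb * (1 - pb))
        r = d / denom
    r[n < min_gametes] = np.nan
    return r, n


def pairwise_ld(haps: HaplotypeSet, max_dist_bp: int = 1_000_000) -> pd.DataFrame:
    """Table of same-chromosome SNP pairs within ``max_dist_bp``.

    Columns: ``marker_i, marker_j, chrom, distance_bp, r, r2``.  Pairs
    where either marker is monomorphic among the shared gametes are skipped.
    """
    records = []
    markers = haps.markers
    for chrom in markers["chrom"].unique():
        cidx = np.flatnonzero((markers["chrom"] == chrom).to_numpy())
        if cidx.size < 2:
            continue
        pos = markers["pos"].to_numpy()[cidx]
        ids = markers["id"].to_numpy()[cidx]
        r, _ = r_matrix(haps.haplotypes[:, cidx])
        iu, ju = np.triu_indices(cidx.size, k=1)
        dist = pos[ju] - pos[iu]
        ok = (dist <= max_dist_bp) & np.isfinite(r[iu, ju])
        n_skipped = int(((dist <= max_dist_bp) & ~np.isfinite(r[iu, ju])).sum())
        if n_skipped:
            logger.debug("pairwise_ld skipped %d undefined pairs on %s", n_skipped, chrom)
        rv = r[iu[ok], ju[ok]]
        records.append(
            pd.DataFrame(
                {
                    "marker_i": ids[iu[ok]],
                    "marker_j": ids[ju[ok]],
                    "chrom": chrom,
                    "distance_bp": dist[ok],
                    "r": rv,
                    "r2": rv**2,
                }
            )
        )
    if not records:
        return pd.DataFrame(columns=["marker_i", "marker_j", "chrom", "distance_bp", "r", "r2"])
    return pd.concat(records, ignore_index=True)


# ---------------------------------------------------------------------------
# Hill-Weir decay fit
# ---------------------------------------------------------------------------

def expected_r2(C: np.ndarray | float, n_gametes: int) -> np.ndarray | float:
    """Drift-recombination expectation of r^2 at scaled recombination ``C``."""
    C = np.asarray(C, dtype=float)
    first = (10 + C) / ((2 + C) * (11 + C))
    second = 1 + ((3 + C) * (12 + 12 * C + C**2)) / (n_gametes * (2 + C) * (11 + C))
    out = first * second
    return float(out) if out.ndim == 0 else out


@dataclass
class DecayFit:
    """Fitted decay curve: ``E[r^2](d) = expected_r2(rho_per_bp * d, n_gametes)``."""

    rho_per_bp: float
    n_gametes: int
    rss: float
    n_pairs: int

    def predict(self, distance_bp: np.ndarray | float) -> np.ndarray | float:
        return expected_r2(self.rho_per_bp * np.asarray(distance_bp, dtype=float), self.n_gametes)


def hill_weir_fit(
    pairs: pd.DataFrame,
    n_gametes: int,
    min_pairs: int = 50,
    starts: tuple[float, ...] = (1e-8, 1e-5, 1e-3),
) -> DecayFit:
    """Least-squares fit of observed r^2 against the decay expectation.

    A single nonnegative parameter (``rho_per_bp``) is fitted by bounded 1-D
    minimization of the residual sum of squares in log-rho space, multi-start
    to guard against local minima.
    """
    d = np.asarray(pairs["distance_bp"], dtype=float)
    y = np.asarray(pairs["r2"], dtype=float)
    ok = np.isfinite(d) & np.isfinite(y)
    d, y = d[ok], y[ok]
    if d.size < min_pairs:
        raise PanelError(f"need >= {min_pairs} pairs to fit the decay curve, got {d.size}")
    if np.unique(d).size < 2:
        raise PanelError("degenerate fit: all pairs at a single distance")

    def rss_log(u: float) -> float:
        resid = y - expected_r2(np.exp(u) * d, n_gametes)
        return float((resid**2).sum())

    lo, hi = np.log(1e-12), np.log(1.0)
    best_u, best_rss = None, np.inf
    for s in starts:
        u0 = np.clip(np.log(s), lo, hi)
        res = optimize.minimize_scalar(
            rss_log, bounds=(max(lo, u0 - 8), min(hi, u0 + 8)), method="bounded",
            options={"xatol": 1e-10},
        )
        if res.success and res.fun < best_rss:
            best_rss, best_u = float(res.fun), float(res.x)
    # one global bounded pass as safety net
    res = optimize.minimize_scalar(rss_log, bounds=(lo, hi), method="bounded", options={"xatol": 1e-10})
    if res.success and res.fun < best_rss:
        best_rss, best_u = float(res.fun), float(res.x)
    if best_u is None:
        raise PanelError("decay fit failed to converge from every start")
    return DecayFit(rho_per_bp=float(np.exp(best_u)), n_gametes=n_gametes, rss=best_rss, n_pairs=d.size)


@dataclass
class DecayDistance:
    distance_bp: float
    status: str  # 'ok' | 'below_threshold' | 'not_reached'

    @property
    def reached(self) -> bool:
        return self.status == "ok"


def decay_distance(
    fit: DecayFit, threshold: float = 0.2, max_search_bp: float = 10_000_000.0
) -> DecayDistance:
    """Distance at which the fitted curve crosses ``threshold``.

    The curve decreases monotonically from its value at d=0 toward the
    asymptote ``1/n``; the root (when bracketed) is found by bisection.
    Returns distance 0 with status ``below_threshold`` when the curve starts
    under the threshold, and status ``not_reached`` when the asymptote is at
    or above the threshold or the crossing lies beyond ``max_search_bp``.
    """
    at0 = expected_r2(0.0, fit.n_gametes)
    if at0 <= threshold:
        return DecayDistance(0.0, "below_threshold")
    if 1.0 / fit.n_gametes >= threshold:
        return DecayDistance(np.inf, "not_reached")
    f = lambda d: fit.predict(d) - threshold
    if f(max_search_bp) > 0:
        return DecayDistance(np.inf, "not_reached")
    root = optimize.brentq(f, 1e-9, max_search_bp, xtol=1e-6)
    return DecayDistance(float(root), "ok")


# ---------------------------------------------------------------------------
# Sampling-design experiments
# ---------------------------------------------------------------------------

def _draw_gametes_by_population(
    haps: HaplotypeSet,
    populations: np.ndarray,
    g_per_pop: int,
    rng: np.random.Generator,
) -> np.ndarray | None:
    """Row indices of ``g_per_pop`` gametes per listed population; None when
    any population has too few gametes."""
    rows = []
    for p in populations:
        idx = np.flatnonzero(haps.populations == p)
        if idx.size < g_per_pop:
            return None
        rows.append(rng.choice(idx, size=g_per_pop, replace=False))
    return np.concatenate(rows)


@dataclass
class SamplingGrid:
    """Mean decay distance per (g, l) cell, NaN where skipped."""

    g_values: list[int]
    l_values: list[int]
    mean_decay_bp: np.ndarray  # rows g, columns l
    n_ok: np.ndarray


def sampling_scheme_ld(
    panel: PopulationPanel,
    l_values: list[int],
    g_values: list[int],
    repeats: int = 10,
    seed: int | np.random.Generator = 0,
    max_dist_bp: int = 1_000_000,
    threshold: float = 0.2,
    min_total_gametes: int = 12,
) -> SamplingGrid:
    """Mean LD decay distance for sampling schemes of ``l`` landraces times
    ``g`` gametes per landrace (cells with ``g*l < 12`` are skipped).

    Per repeat: draw ``l`` populations, then ``g`` gametes per population
    without replacement; pool; compute pairwise LD and fit the decay curve
    with ``n = g*l`` gametes; record the threshold decay distance.
    """
    haps = panel.to_haplotype_set()
    pops = np.array(panel.population_labels, dtype=object)
    rng = np.random.default_rng(seed)
    mean_grid = np.full((len(g_values), len(l_values)), np.nan)
    n_ok = np.zeros((len(g_values), len(l_values)), dtype=int)
    for gi, g in enumerate(g_values):
        for li, l in enumerate(l_values):
            if g * l < min_total_gametes or l > len(pops):
                continue
            vals = []
            for _ in range(repeats):
                chosen_pops = rng.choice(pops, size=l, replace=False)
                rows = _draw_gametes_by_population(haps, chosen_pops, g, rng)
                if rows is None:
                    logger.info("cell g=%d l=%d skipped: population too small", g, l)
                    break
                sub = haps.take_gametes(rows)
                try:
                    table = pairwise_ld(sub, max_dist_bp)
                    fit = hill_weir_fit(table, n_gametes=g * l)
                except PanelError:
                    continue
                dd = decay_distance(fit, threshold)
                if dd.reached or dd.status == "below_threshold":
                    vals.append(dd.distance_bp)
            if vals:
                mean_grid[gi, li] = float(np.mean(vals))
                n_ok[gi, li] = len(vals)
    return SamplingGrid(g_values=list(g_values), l_values=list(l_values), mean_decay_bp=mean_grid, n_ok=n_ok)


def sample_size_ld(
    panel: PopulationPanel,
    population: str,
    sizes: list[int],
    repeats: int = 10,
    seed: int | np.random.Generator = 0,
    max_dist_bp: int = 1_000_000,
    threshold: float = 0.2,
) -> pd.DataFrame:
    """Mean and variance of the decay distance at varying within-population
    sample sizes (individuals).  Output rows sorted by ascending size."""
    idx = panel.individuals_of(population)
    sizes_sorted = sorted(sizes)
    if sizes_sorted[-1] > idx.size:
        raise PanelError(
            f"population {population!r} has {idx.size} individuals, cannot draw {sizes_sorted[-1]}"
        )
    rng = np.random.default_rng(seed)
    rows = []
    for size in sizes_sorted:
        vals = []
        for _ in range(repeats):
            chosen = rng.choice(idx, size=size, replace=False)
            sub = panel.take_samples(np.sort(chosen))
            try:
                table = pairwise_ld(sub.to_haplotype_set(), max_dist_bp)
                fit = hill_weir_fit(table, n_gametes=2 * size)
            except PanelError:
                continue
            dd = decay_distance(fit, threshold)
            if dd.reached or dd.status == "below_threshold":
                vals.append(dd.distance_bp)
        vals = np.array(vals)
        rows.append(
            {
                "size": size,
                "n_estimates": vals.size,
                "mean_decay_bp": float(vals.mean()) if vals.size else np.nan,
                "var_decay_bp": float(vals.var(ddof=1)) if vals.size > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def interchromosomal_ld(
    panel: PopulationPanel,
    l: int,
    n_individuals: int = 24,
    maf_bin_width: float = 0.05,
    snps_per_bin_per_chrom: int = 100,
    r2_threshold: float = 0.2,
    repeats: int = 10,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Per-repeat fraction of cross-chromosome SNP pairs with ``r^2`` above
    the threshold, for ``n_individuals`` drawn from ``l`` populations.

    SNPs are binned by sample minor-allele frequency in steps of
    ``maf_bin_width``; per bin and chromosome, ``snps_per_bin_per_chrom``
    SNPs are drawn (underfilled bins are skipped) so the frequency spectrum
    is matched across compositions.
    """
    if n_individuals % l != 0:
        raise PanelError(f"l={l} must divide n_individuals={n_individuals}")
    pops = np.array(panel.population_labels, dtype=object)
    if l > len(pops):
        raise PanelError(f"panel has {len(pops)} populations, cannot draw {l}")
    if panel.markers["chrom"].nunique() < 2:
        raise PanelError("interchromosomal LD needs at least 2 chromosomes")
    per_pop = n_individuals // l
    rng = np.random.default_rng(seed)
    fractions = np.empty(repeats)
    chrom_arr = panel.markers["chrom"].to_numpy()
    for rep in range(repeats):
        chosen_pops = rng.choice(pops, size=l, replace=False)
        ind_rows = []
        for p in chosen_pops:
            idx = panel.individuals_of(p)
            if idx.size < per_pop:
                raise PanelError(f"population {p!r} has fewer than {per_pop} individuals")
            ind_rows.append(rng.choice(idx, size=per_pop, replace=False))
        sub = panel.take_samples(np.sort(np.concatenate(ind_rows)))
        haps = sub.to_haplotype_set()
        H = haps.haplotypes
        Mc = H != MISSING
        with np.errstate(invalid="ignore"):
            p_alt = np.where(Mc, H, 0).sum(axis=0) / Mc.sum(axis=0)
        maf = np.minimum(p_alt, 1 - p_alt)
        poly = (maf > 0) & np.isfinite(maf)
        n_bins = int(round(0.5 / maf_bin_width))
        bin_idx = np.minimum((maf / maf_bin_width).astype(int), n_bins - 1)
        selected: list[np.ndarray] = []
        for b in range(n_bins):
            for chrom in pd.unique(chrom_arr):
                cand = np.flatnonzero(poly & (bin_idx == b) & (chrom_arr == chrom))
                if cand.size < snps_per_bin_per_chrom:
                    logger.debug("bin %d on %s underfilled (%d)", b, chrom, cand.size)
                    continue
                selected.append(rng.choice(cand, size=snps_per_bin_per_chrom, replace=False))
        if not selected:
            raise PanelError("every MAF bin underfilled; lower snps_per_bin_per_chrom")
        sel = np.sort(np.concatenate(selected))
        if len(pd.unique(chrom_arr[sel])) < 2:
            raise PanelError("fewer than 2 chromosomes with sampled SNPs")
        r, _ = r_matrix(H[:, sel])
        iu, ju = np.triu_indices(sel.size, k=1)
        cross = chrom_arr[sel][iu] != chrom_arr[sel][ju]
        rv = r[iu, ju][cross]
        rv = rv[np.isfinite(rv)]
        fractions[rep] = float((rv**2 > r2_threshold).mean())
    return fractions


def interchromosomal_comparison(
    panel: PopulationPanel,
    l_values: list[int],
    repeats: int = 10,
    seed: int = 0,
    **kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Interchromosomal-LD fractions for several compositions plus
    Wilcoxon rank-sum tests of each ``l > 1`` against ``l = 1``
    (two-sided, Bonferroni-corrected)."""
    if 1 not in l_values:
        raise PanelError("comparison requires l = 1 as the baseline")
    rng_root = np.random.default_rng(seed)
    fractions = {}
    for l in l_values:
        fractions[l] = interchromosomal_ld(
            panel, l=l, repeats=repeats, seed=rng_root.integers(2**31), **kwargs
        )
    frac_df = pd.DataFrame(
        [(l, rep, v) for l, arr in fractions.items() for rep, v in enumerate(arr)],
        columns=["l", "repeat", "fraction_r2_gt_threshold"],
    )
    comparisons = [l for l in l_values if l != 1]
    rows = []
    for l in comparisons:
        stat, p = stats.ranksums(fractions[l], fractions[1])
        rows.append(
            {
                "l": l,
                "statistic": stat,
                "p_value": p,
                "p_bonferroni": min(1.0, p * len(comparisons)),
            }
        )
    return frac_df, pd.DataFrame(rows)
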