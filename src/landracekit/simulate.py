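"""Forward Wright-Fisher simulation of structured landrace-like panels.

The generator emulates the structure of a multi-landrace SNP panel: an
ancestral pool of standing variation splits into isolated populations that
random-mate (optionally partially selfing) for ``split_generations``
generations with recombination, after which diploid individuals are drawn.
No new mutation arises after the split, so differentiation is pure drift with
expected fixation index ``F_ST = 1 - (1 - 1/(2 N))^t``.

The timescale is deliberately compressed: small within-population sizes and
few generations reach the target differentiation quickly, and the
recombination rate per bp is scaled up so that the product
``generations x recombination`` — which sets the physical scale of linkage
disequilibrium — matches the hundreds-of-kb decay distances typical of maize
landraces.  Optional array-style ascertainment retains only SNPs exceeding a
minor-allele-frequency bound in a small discovery subset, enriching
intermediate frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .panel import MISSING, MARKER_COLUMNS, PanelError, PopulationPanel


@dataclass
class SimulationConfig:
    """Parameters of the structured random-mating panel simulator.

    Defaults describe the study conditions emulated throughout: 10
    populations of 24 diploid individuals, 10 chromosomes of 2 Mb carrying
    200 SNPs each, drift calibrated so the expected F_ST is ~0.27, and
    recombination calibrated so within-population LD decays over 10^2-10^3 kb.
    """

    n_pops: int = 10
    n_ind_per_pop: int = 24
    n_chrom: int = 10
    chrom_length_bp: int = 2_000_000
    n_snps_per_chrom: int = 200
    ancestral_ne: int = 10_000
    split_generations: int = 31
    within_pop_ne: int = 50
    recomb_rate_per_bp: float = 5e-8
    missing_rate: float = 0.0
    selfing_rate: float = 0.0
    ascertainment_maf: float = 0.0
    ancestral_burnin_generations: int = 0
    ancestral_pool_size: int = 60
    seed: int = 0

    def validate(self) -> None:
        counts = dict(
            n_pops=self.n_pops,
            n_ind_per_pop=self.n_ind_per_pop,
            n_chrom=self.n_chrom,
            chrom_length_bp=self.chrom_length_bp,
            n_snps_per_chrom=self.n_snps_per_chrom,
            ancestral_ne=self.ancestral_ne,
            within_pop_ne=self.within_pop_ne,
        )
        for name, v in counts.items():
            if v < 1:
                raise ValueError(f"{name} must be >= 1, got {v}")
        for name, v in dict(
            missing_rate=self.missing_rate,
            selfing_rate=self.selfing_rate,
            ascertainment_maf=self.ascertainment_maf,
            recomb_rate_per_bp=self.recomb_rate_per_bp,
        ).items():
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.split_generations < 0:
            raise ValueError("split_generations must be >= 0")
        if self.ancestral_burnin_generations < 0:
            raise ValueError("ancestral_burnin_generations must be >= 0")
        if self.ancestral_pool_size < 1:
            raise ValueError("ancestral_pool_size must be >= 1")
        if self.chrom_length_bp < self.n_snps_per_chrom:
            raise ValueError("chrom_length_bp must be >= n_snps_per_chrom")
        if self.n_ind_per_pop > self.within_pop_ne:
            raise ValueError("cannot draw more individuals than within_pop_ne")


@dataclass
class TruthRecord:
    """Ground truth stored alongside every simulated panel."""

    expected_fst: float
    split_generations: int
    within_pop_ne: int
    recomb_rate_per_bp: float
    seed: int
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def single_landrace_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Study conditions for within-landrace analyses: one old open-pollinated
    population large enough to subsample (48 individuals drawn from Ne=60),
    drifted for 100 generations so linkage disequilibrium decays over a few
    hundred kb — the scale observed within real maize landraces."""
    fields = dict(
        n_pops=1,
        n_ind_per_pop=48,
        within_pop_ne=60,
        split_generations=100,
        n_snps_per_chrom=600,
        recomb_rate_per_bp=5e-8,
        seed=seed,
    )
    fields.update(overrides)
    return SimulationConfig(**fields)


def phase_pair_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Study conditions for between-population linkage-phase analyses: two
    populations that split from a finite ancestral pool carrying linkage
    disequilibrium built up over a 100-generation burn-in, then drifted
    apart for 31 generations.  Shared ancestral LD decays with recombination
    distance, so linkage-phase agreement between the populations falls off
    with physical distance."""
    fields = dict(
        n_pops=2,
        n_ind_per_pop=48,
        within_pop_ne=60,
        split_generations=31,
        ancestral_burnin_generations=100,
        ancestral_pool_size=60,
        n_snps_per_chrom=600,
        recomb_rate_per_bp=5e-8,
        seed=seed,
    )
    fields.update(overrides)
    return SimulationConfig(**fields)


def expected_drift_fst(within_pop_ne: int, split_generations: int) -> float:
    """Expected fixation index after t generations of pure drift at size N."""
    return 1.0 - (1.0 - 1.0 / (2.0 * within_pop_ne)) ** split_generations


def _draw_ancestral_frequencies(rng: np.random.Generator, n_snps: int, ne: int) -> np.ndarray:
    """Frequencies from a density proportional to 1/x on [1/(2Ne), 1 - 1/(2Ne)].

    Inverse-CDF sampling: x = lo * (hi/lo)^u for u ~ U(0,1).  This
    approximates the neutral equilibrium spectrum, for which the expected
    sample SFS is proportional to 1/i.
    """
    lo = 1.0 / (2.0 * ne)
    hi = 1.0 - lo
    u = rng.random(n_snps)
    return lo * (hi / lo) ** u


def _meiosis_generation(
    rng: np.random.Generator,
    haplotypes: np.ndarray,
    chrom_starts: np.ndarray,
    positions: np.ndarray,
    chrom_length_bp: int,
    recomb_rate_per_bp: float,
    selfing_rate: float,
) -> np.ndarray:
    """One Wright-Fisher generation: returns the offspring gamete matrix.

    ``haplotypes`` is (2N, m); gametes 2i, 2i+1 belong to parent i.  Each of
    the N offspring draws two parents (identical with probability
    ``selfing_rate``) and receives one recombinant gamete from each.
    """
    n = haplotypes.shape[0] // 2
    m = haplotypes.shape[1]
    n_chrom = len(chrom_starts) - 1
    mothers = rng.integers(0, n, size=n)
    fathers = rng.integers(0, n, size=n)
    self_mask = rng.random(n) < selfing_rate
    fathers[self_mask] = mothers[self_mask]
    parents = np.empty(2 * n, dtype=np.int64)
    parents[0::2] = mothers
    parents[1::2] = fathers

    mean_xo = recomb_rate_per_bp * chrom_length_bp
    n_xo = rng.poisson(mean_xo, size=(2 * n, n_chrom))
    start_phase = rng.integers(0, 2, size=(2 * n, n_chrom))

    offspring = np.empty_like(haplotypes)
    # fast path: gametes with no crossover on any chromosome copy whole rows
    for g in range(2 * n):
        p = parents[g]
        h0 = haplotypes[2 * p]
        h1 = haplotypes[2 * p + 1]
        if not n_xo[g].any():
            # still need per-chromosome phase choice
            row = np.empty(m, dtype=haplotypes.dtype)
            for c in range(n_chrom):
                s, e = chrom_starts[c], chrom_starts[c + 1]
                row[s:e] = (h1 if start_phase[g, c] else h0)[s:e]
            offspring[g] = row
            continue
        row = np.empty(m, dtype=haplotypes.dtype)
        for c in range(n_chrom):
            s, e = chrom_starts[c], chrom_starts[c + 1]
            k = n_xo[g, c]
            if k == 0:
                row[s:e] = (h1 if start_phase[g, c] else h0)[s:e]
                continue
            breaks = np.sort(rng.uniform(0, chrom_length_bp, size=k))
            # which parental haplotype each SNP copies: phase flips at each break
            n_before = np.searchsorted(breaks, positions[s:e])
            chooser = (start_phase[g, c] + n_before) % 2
            seg = np.where(chooser == 0, h0[s:e], h1[s:e])
            row[s:e] = seg
        offspring[g] = row
    return offspring


def _found_from_pool(
    rng: np.random.Generator,
    pool: np.ndarray,
    n_founders: int,
    chrom_starts: np.ndarray,
    positions: np.ndarray,
    chrom_length_bp: int,
    recomb_rate_per_bp: float,
) -> np.ndarray:
    """2*n_founders gametes produced by meiosis from random pool parents."""
    n_pool = pool.shape[0] // 2
    m = pool.shape[1]
    n_chrom = len(chrom_starts) - 1
    out = np.empty((2 * n_founders, m), dtype=pool.dtype)
    parents = rng.integers(0, n_pool, size=2 * n_founders)
    n_xo = rng.poisson(recomb_rate_per_bp * chrom_length_bp, size=(2 * n_founders, n_chrom))
    start_phase = rng.integers(0, 2, size=(2 * n_founders, n_chrom))
    for g in range(2 * n_founders):
        h0 = pool[2 * parents[g]]
        h1 = pool[2 * parents[g] + 1]
        for c in range(n_chrom):
            s, e = chrom_starts[c], chrom_starts[c + 1]
            k = n_xo[g, c]
            if k == 0:
                out[g, s:e] = (h1 if start_phase[g, c] else h0)[s:e]
                continue
            breaks = np.sort(rng.uniform(0, chrom_length_bp, size=k))
            chooser = (start_phase[g, c] + np.searchsorted(breaks, positions[s:e])) % 2
            out[g, s:e] = np.where(chooser == 0, h0[s:e], h1[s:e])
    return out


def simulate_panel(config: SimulationConfig) -> tuple[PopulationPanel, TruthRecord]:
    """Simulate a phased multi-population panel with known drift/LD truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    m_per = config.n_snps_per_chrom
    m = m_per * config.n_chrom
    # distinct integer positions, 1-based, sorted per chromosome
    positions = np.empty(m, dtype=np.int64)
    chroms = np.empty(m, dtype=object)
    for c in range(config.n_chrom):
        pos = rng.choice(np.arange(1, config.chrom_length_bp + 1), size=m_per, replace=False)
        positions[c * m_per : (c + 1) * m_per] = np.sort(pos)
        chroms[c * m_per : (c + 1) * m_per] = f"chr{c + 1}"
    chrom_starts = np.arange(0, m + m_per, m_per)

    freqs = _draw_ancestral_frequencies(rng, m, config.ancestral_ne)

    n = config.within_pop_ne

    # optional burn-in: evolve a finite ancestral pool so that the split
    # populations share ancestral linkage disequilibrium (linkage phase)
    ancestral_pool: np.ndarray | None = None
    if config.ancestral_burnin_generations > 0:
        pool = (rng.random((2 * config.ancestral_pool_size, m)) < freqs).astype(np.int8)
        for _ in range(config.ancestral_burnin_generations):
            pool = _meiosis_generation(
                rng, pool, chrom_starts, positions, config.chrom_length_bp,
                config.recomb_rate_per_bp, config.selfing_rate,
            )
        ancestral_pool = pool

    pop_gametes: list[np.ndarray] = []
    for _ in range(config.n_pops):
        if ancestral_pool is None:
            haps = (rng.random((2 * n, m)) < freqs).astype(np.int8)
        else:
            # founders are offspring of the shared ancestral pool
            haps = _found_from_pool(
                rng, ancestral_pool, n, chrom_starts, positions,
                config.chrom_length_bp, config.recomb_rate_per_bp,
            )
        for _ in range(config.split_generations):
            haps = _meiosis_generation(
                rng,
                haps,
                chrom_starts,
                positions,
                config.chrom_length_bp,
                config.recomb_rate_per_bp,
                config.selfing_rate,
            )
        chosen = rng.choice(n, size=config.n_ind_per_pop, replace=False)
        idx = np.empty(2 * chosen.size, dtype=np.int64)
        idx[0::2] = 2 * chosen
        idx[1::2] = 2 * chosen + 1
        pop_gametes.append(haps[idx])

    haplotypes = np.vstack(pop_gametes)
    n_total = config.n_pops * config.n_ind_per_pop
    populations = np.repeat([f"P{i + 1}" for i in range(config.n_pops)], config.n_ind_per_pop)
    samples = [f"{p}_I{j + 1}" for p in [f"P{i + 1}" for i in range(config.n_pops)]
               for j in range(config.n_ind_per_pop)]

    # remove sites fixed in the drawn panel
    p_panel = haplotypes.mean(axis=0)
    keep = (p_panel > 0) & (p_panel < 1)

    # array-style ascertainment on a small cross-population discovery subset
    if config.ascertainment_maf > 0:
        disc_ind = _discovery_subset(rng, populations, n_subset=8)
        disc_rows = np.concatenate([(2 * disc_ind), (2 * disc_ind + 1)])
        p_disc = haplotypes[disc_rows].mean(axis=0)
        maf_disc = np.minimum(p_disc, 1 - p_disc)
        keep &= maf_disc >= config.ascertainment_maf
        if not keep.any():
            raise PanelError(
                "ascertainment removed every site; lower ascertainment_maf"
            )
    if not keep.any():
        raise PanelError("no polymorphic sites in the drawn panel; increase n_snps or Ne")
    kept = np.flatnonzero(keep)
    haplotypes = haplotypes[:, kept]

    markers = pd.DataFrame(
        {
            "chrom": chroms[kept],
            "pos": positions[kept],
            "id": [f"{c}_{p}" for c, p in zip(chroms[kept], positions[kept])],
            "ref": "A",
            "alt": "G",
        },
        columns=MARKER_COLUMNS,
    )
    genotypes = (haplotypes[0::2].astype(np.int16) + haplotypes[1::2].astype(np.int16)).astype(np.int8)
    panel = PopulationPanel(
        markers=markers,
        genotypes=genotypes,
        samples=samples,
        populations=populations,
        phased=True,
        haplotypes=haplotypes,
        meta={"simulation_seed": config.seed},
    )
    if config.missing_rate > 0:
        panel = apply_missingness(panel, config.missing_rate, rng)

    truth = TruthRecord(
        expected_fst=expected_drift_fst(config.within_pop_ne, config.split_generations),
        split_generations=config.split_generations,
        within_pop_ne=config.within_pop_ne,
        recomb_rate_per_bp=config.recomb_rate_per_bp,
        seed=config.seed,
        config=asdict(config),
    )
    return panel, truth


def _discovery_subset(rng: np.random.Generator, populations: np.ndarray, n_subset: int) -> np.ndarray:
    """Indices of discovery individuals: one per population from n_subset populations
    drawn across the panel (all populations when fewer than n_subset exist)."""
    labels = pd.unique(populations)
    k = min(n_subset, len(labels))
    chosen_pops = rng.choice(labels, size=k, replace=False)
    out = []
    for p in chosen_pops:
        idx = np.flatnonzero(populations == p)
        out.append(rng.choice(idx))
    return np.array(out, dtype=np.int64)


def apply_missingness(
    panel: PopulationPanel, rate: float, seed: int | np.random.Generator
) -> PopulationPanel:
    """Set each genotype (both gametes) missing independently with probability ``rate``."""
    if not 0 <= rate < 1:
        raise ValueError("missing rate must lie in [0, 1)")
    if rate == 0:
        return panel
    rng = np.random.default_rng(seed)
    mask = rng.random(panel.genotypes.shape) < rate
    genotypes = panel.genotypes.copy()
    genotypes[mask] = MISSING
    haplotypes = None
    if panel.haplotypes is not None:
        haplotypes = panel.haplotypes.copy()
        gmask = np.repeat(mask, 2, axis=0)
        haplotypes[gmask] = MISSING
    return PopulationPanel(
        markers=panel.markers.copy(),
        genotypes=genotypes,
        samples=list(panel.samples),
        populations=panel.populations.copy(),
        phased=panel.phased,
        haplotypes=haplotypes,
        meta=dict(panel.meta),
    )
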