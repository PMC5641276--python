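# Methods

Definitions, model assumptions, parameter choices and known limitations of
the statistics implemented in `landracekit`.

## Data model

A `PopulationPanel` holds bi-allelic SNPs (`chrom, pos, id, ref, alt`),
a dosage matrix (individuals × markers, values 0/1/2, −1 = missing), a
population label per individual, and — when the source VCF is fully
phased — a gamete (haplotype) matrix with rows `2i, 2i+1` belonging to
individual `i`. Filtering applies the marker call-rate threshold first,
then the sample threshold on the reduced matrix. Panel intersection keeps
markers shared by chromosome/position, recodes dosages `d → 2 − d` when
ref/alt are swapped, and drops pairs with incompatible alleles.

## Estimators

**Folded SFS.** For each SNP, `g = floor(2nc)` gametes are drawn without
replacement from the called gametes (`c` = call-rate floor) and the minor
count in the draw is binned; masses accumulate over SNPs and 200–1000
resampling repeats. The draw is a hypergeometric variable and is computed
as such (vectorized), rather than by materializing gamete subsets; an
exhaustive-enumeration oracle in the tests confirms exactness. The default
accumulates one class observation per SNP and repeat (`method="mass"`);
`method="rounded"` instead averages each SNP's minor count over repeats
and bins once — an alternative reading of "averaged over 1000 random
samples" that is also exposed. The neutral reference is
`E[f_i] = (1/i)/Σ_{j<g} 1/j`, folded by adding classes `i` and `g − i`.

**Diversity.** PP is the fraction of markers with both alleles observed.
Per-marker π uses the unbiased pairwise mismatch `(k/(k−1))·2p(1−p)` over
`k` called gametes. Window H anchors one window `[pos, pos + 100 kb)` at
each SNP (≥ 5 SNPs, complete gametes only) and applies the analogous
`(k/(k−1))(1 − Σx_c²)` over haplotype classes. F_is is the
Weir–Cockerham single-population estimator; its permutation null re-pairs
the called alleles of each locus uniformly at random (Hardy–Weinberg
null) and the two-sided p-value uses +1 smoothing.

**AMOVA.** One-level decomposition on squared distances:
`SS_total = Σ_{i<j} d²/N`, within sums the per-population analogue, and
`σ²_among = (SS_among/df − σ²_w)/n₀` with the standard unbalanced-size
`n₀`. Negative among-components are clamped to zero in the report, but
permutations compare the *unclamped* Φ — clamping would put a point mass
in the null distribution and break p-value uniformity. When the panel is
phased, `amova_gametic` treats gametes as the molecular units (gamete
distance = √(fraction of differing alleles)) and permutes whole
individuals. This matters: with individuals as units the within-individual
gametic stratum is collapsed and Φ inflates to ≈ 2F/(1+F) under
Hardy–Weinberg proportions; with gametes as units Φ estimates the drift
fixation index F itself, which simulations confirm.

**Variance captured by l landraces.** Per repeat, the P populations are
randomly partitioned into `ceil(P/l)` groups (the last group takes the
remainder); each group's captured proportion is its mean squared
deviation `SS_total/df_total` divided by the full panel's. The underlying
study does not print a formula for "proportion of variance captured"; the
MSD ratio is one defensible reading (alternatives, e.g. 1 − the
among-groups component, exist). Note that when `l` does not divide P the
remainder group depresses the pooled mean; comparisons across `l` are
cleanest at divisors of P.

**Structure.** The modified Rogers' distance between individuals is the
root mean square of dosage/2 differences over mutually called markers
(0 = identical, 1 = opposite homozygotes). Neighbor joining is the
classical agglomeration with deterministic lowest-index tie-breaks and
negative branch lengths clamped to zero (deficit moved to the sibling);
scikit-bio's implementation serves as a topology oracle in the tests.
PCoA is Gower double-centering with eigendecomposition; negative
eigenvalues are reported but carry no axes. The Mantel test is one-sided
(≥) with +1 smoothing. The Procrustes statistic is `sqrt(1 − ss)` on the
first k axes with scaling, rotation *and reflection* allowed —
appropriate since ordination axes have arbitrary sign. LD pruning scans
sliding SNP windows greedily and removes the lower-MAF member of any pair
with r² above threshold (tie: later position).

**LD.** The signed gametic correlation
`r = (p_AB − p_A p_B)/√(p_A(1−p_A)p_B(1−p_B))` is computed missing-aware
via three matrix products, each pair using exactly the gametes called at
both markers. The expected decay under drift–recombination balance is

    E[r²](C) = (10+C)/((2+C)(11+C)) · [1 + (3+C)(12+12C+C²)/(n(2+C)(11+C))]

with `C = ρ·d` and `n` sampled gametes; `ρ` (per bp) is the single fitted
parameter, estimated by bounded 1-D least squares in log-ρ space with
multi-start. The curve's large-C asymptote is `1/n`, so the r² = 0.2
decay distance is flagged `not_reached` whenever `1/n ≥ 0.2` (e.g. 4
gametes) and `below_threshold` when the curve starts under the threshold.
The sampling experiments draw `l` landraces × `g` gametes (decay-distance
grid), varying within-landrace sample sizes, and MAF-matched SNP subsets
for the interchromosomal r² fraction with Wilcoxon rank-sum comparisons
against the single-landrace baseline.

**Phase persistence.** For marker pairs ≤ 1 Mb apart that are polymorphic
in both gamete sets, signed r values are compared per `(k·10 kb,
(k+1)·10 kb]` bin: Pearson correlation of the paired r values, and PEP =
fraction of pairs with `r_A·r_B > 0`. Pairs with a zero product have
undefined sign and are excluded from PEP (their count is reported).
Split-half controls randomly halve one population and repeat the
comparison.

## Simulator

Forward Wright–Fisher with recombination:

1. **Ancestral frequencies** are drawn from the neutral density ∝ 1/x
   truncated to `[1/(2N_anc), 1 − 1/(2N_anc)]` by inverse-CDF sampling —
   the stationary frequency spectrum of a neutral locus, so an
   undiverged panel reproduces the 1/i folded SFS.
2. An optional **ancestral burn-in** evolves a finite pool
   (`ancestral_pool_size`, default off) for `ancestral_burnin_generations`
   before the split, creating the shared ancestral LD that phase-persistence
   analyses require. Without it the ancestral pool is in linkage
   equilibrium (which is what the SFS calibration wants).
3. Each population is founded from the pool and drifts independently for
   `split_generations` at size `within_pop_ne`; meiosis places Poisson
   crossovers (`recomb_rate_per_bp × chrom_length`) per gamete, with
   optional selfing. The expected fixation index is
   `F = 1 − (1 − 1/(2N))^t`, recorded per run in a `TruthRecord`.
4. Optional **array ascertainment** keeps only SNPs whose MAF in a small
   cross-population discovery subset (8 individuals) exceeds a threshold;
   fixed sites are always removed. Optional genotype missingness masks
   both gametes of a call.

**Timescale compression.** Real landraces diverged over centuries at
effective sizes of thousands. Simulating that directly is unnecessary:
drift depends on t/N and LD on N·ρ·d, so small N and t with a rescaled
recombination rate reproduce the same observable regime in seconds. The
shipped configurations are calibrated this way:

- default (`SimulationConfig()`): 10 populations × 24 individuals,
  N = 50, t = 31 → F = 0.268, matching a ~27 % among-landrace AMOVA
  share;
- `single_landrace_config()`: one population of 48, N = 60, t = 100,
  ρ = 5·10⁻⁸/bp → within-landrace decay distance ≈ 3·10⁵ bp, inside the
  10²–10³ kb within-landrace regime;
- `phase_pair_config()`: two populations of 48 with a 100-generation
  burn-in pool of 60, so they inherit strong shared ancestral LD.

These were fixed from the analytic targets before the acceptance checks
were run, not tuned against them.

## Numerical and reproducibility choices

- All randomness flows through `numpy.random.default_rng`; pipeline
  stages get independent seeds via `sha256(f"{master}:{stage}") mod 2³¹`,
  so adding a stage never perturbs another stage's stream.
- Pipeline outputs contain no timestamps; a rerun with the same config
  and seed is bit-identical (the manifest hashes the scientific config,
  excluding the output directory).
- Permutation p-values use +1 smoothing `((#extreme)+1)/(n+1)` and are
  validated for uniformity under exchangeable nulls (KS test) in the
  acceptance suite.
- Matrix-product implementations of r, MRD and gamete distances are
  checked to 1e-12 against brute-force counting oracles.

## Scope and limitations

- SNPs are bi-allelic and neutral; no mutation after the split, no
  migration, no selection, no population-size changes. Landrace panels
  with admixture or strong outcrossing structure violate these
  assumptions.
- The simulator's marker positions are uniform per chromosome and
  recombination is homogeneous — no hotspots, no interference.
- `amova` is one-level (within/among); hierarchical designs (regions >
  landraces) are out of scope.
- The Hill–Weir fit assumes drift–recombination equilibrium; panels far
  from equilibrium (recent bottlenecks, admixture LD) bias ρ̂.
- NJ ties are broken deterministically rather than randomized; for
  distance matrices with exact ties the topology is reproducible but one
  of several equally valid resolutions.
- The capture-curve partition places the remainder in the last group;
  see the estimator note above when `l` does not divide the number of
  populations.
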