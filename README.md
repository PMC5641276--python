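# landracekit

Diversity, linkage disequilibrium (LD) and linkage-phase statistics for
structured crop populations — landraces — plus a forward Wright–Fisher
simulator to validate every estimator against known truth.

## The scientific problem

Crop landraces are genetically heterogeneous, locally adapted populations.
Questions that recur when genotyping panels of them:

- **How is diversity distributed?** Within-landrace statistics (proportion
  of polymorphic markers, per-marker nucleotide diversity π, windowed
  haplotype heterozygosity H, the inbreeding coefficient F_is) and the
  within/among decomposition (AMOVA with its Φ_ST statistic). How many
  landraces does a breeding program need to sample to capture most of the
  total molecular variance?
- **How far does LD extend?** Within one landrace, LD decays over hundreds
  of kilobases; pooling individuals across landraces collapses it by orders
  of magnitude, and mixing also *creates* spurious LD between chromosomes.
  The package fits the drift–recombination expectation of r² (the
  Hill–Weir curve with sample-size correction) and reports the distance at
  which it crosses r² = 0.2, over configurable sampling schemes
  (l landraces × g gametes).
- **Is linkage phase shared?** Whether a marker pair sits in coupling or
  repulsion (the sign of r) persists across landraces that share ancestral
  LD. The package measures this per 10-kb distance bin as the correlation
  of signed r and the proportion of equal-sign pairs (PEP), with
  split-half controls.
- **Is the marker panel biased?** Array SNPs discovered in a small panel
  over-represent intermediate frequencies. The folded site-frequency
  spectrum (SFS), estimated by repeated gamete subsampling, is compared
  against the neutral coalescent expectation E[f_i] ∝ 1/i.

Because the real datasets behind such studies are large and external, the
package ships a calibrated forward simulator: populations drift apart from
a shared ancestral pool for a known number of generations, so every
statistic can be checked against an analytic expectation (for example
F = 1 − (1 − 1/2N)^t). See `docs/methods.md` for the model.

## Worked example

```python
from landracekit import SimulationConfig, simulate_panel, mrd, variance_captured
from landracekit.amova import amova_gametic

# 10 landraces x 24 individuals, drifted to an expected fixation index of
# F = 1 - (1 - 1/100)**31 = 0.268
panel, truth = simulate_panel(SimulationConfig(n_snps_per_chrom=450, seed=1))

res = amova_gametic(panel, n_perms=999, seed=0)
print(truth.expected_fst)   # 0.2677
print(res.phi_st)           # 0.274  (gametic AMOVA recovers the drift F)
print(res.pct_among)        # 27.4 % among landraces, 72.6 % within

curve = variance_captured(mrd(panel).values, panel.populations,
                          l_values=[1, 2, 5], n_repeats=400, seed=8)
print(curve.means())        # {1: 0.59, 2: 0.82, 5: 0.96}
                            # five landraces capture ~96 % of the variance
```

LD decay within one deep-LD landrace:

```python
from landracekit import (single_landrace_config, simulate_panel,
                         pairwise_ld, hill_weir_fit, decay_distance)

panel, _ = simulate_panel(single_landrace_config(seed=1))
pairs = pairwise_ld(panel.to_haplotype_set())            # r, r2 per SNP pair
fit = hill_weir_fit(pairs, n_gametes=2 * panel.n_individuals)
print(decay_distance(fit, threshold=0.2).distance_bp)    # ~3e5 bp
```

The same analyses are available from the command line
(`landracekit --help`): `simulate`, `filter`, `sfs`, `diversity`, `amova`,
`capture-curve`, `structure {mrd,njt,pcoa,mantel,procrustes,prune}`,
`ld {pairs,fit,grid,interchrom,samplesize}`, `phase`, and `run` for a full
YAML-configured pipeline with a deterministic manifest.

## Repository layout

- `src/landracekit/` — the library: `panel` (VCF I/O, filtering,
  sampling designs), `simulate`, `sfs`, `diversity`, `amova`, `structure`,
  `ld`, `phase`, `pipeline`, `cli`.
- `analysis/` — numbered driver scripts that run the full study on
  simulated panels and write tables under `results/`.
- `scripts/acceptance.py` — one-shot summary of the headline quantities.
- `tests/` — unit tests against hand-worked and independent-library
  oracles (scikit-bio, dendropy, scipy), plus `tests/test_acceptance.py`
  with the study-level property checks.
- `docs/methods.md` — model, estimator definitions, numerical choices,
  and limitations.

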