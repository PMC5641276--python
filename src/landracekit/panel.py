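"""Genotype panels: reading, writing, filtering and sampling.

The central container is :class:`PopulationPanel`, a diploid SNP genotype
matrix (alt-allele dosages 0/1/2, ``-1`` for missing) together with a marker
map and a sample -> population (landrace) partition.  Phased panels
additionally carry a gametes x markers haplotype matrix from which a
:class:`HaplotypeSet` can be extracted for LD and linkage-phase statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

MARKER_COLUMNS = ["chrom", "pos", "id", "ref", "alt"]


class PanelError(ValueError):
    """Raised for malformed or inconsistent panel inputs."""


def _as_marker_frame(markers: pd.DataFrame) -> pd.DataFrame:
    missing_cols = [c for c in MARKER_COLUMNS if c not in markers.columns]
    if missing_cols:
        raise PanelError(f"marker table lacks columns {missing_cols}")
    return markers.reset_index(drop=True)


@dataclass
class PopulationPanel:
    """Diploid SNP genotypes for a set of individuals partitioned into populations.

    Attributes
    ----------
    markers : pandas.DataFrame
        One row per SNP with columns ``chrom, pos, id, ref, alt``; sorted by
        (chrom, pos), positions 1-based.
    genotypes : numpy.ndarray, shape (n_individuals, n_markers), int8
        Alt-allele dosage in {0, 1, 2}; ``-1`` encodes a missing call.
    samples : list of str
        Individual identifiers, row order of ``genotypes``.
    populations : numpy.ndarray of str
        Population (landrace) label per individual.
    phased : bool
        True when gametic phase is known for every non-missing call.
    haplotypes : numpy.ndarray or None, shape (2 * n_individuals, n_markers), int8
        Gamete alleles in {0, 1}, ``-1`` missing; rows ``2i`` and ``2i+1``
        are the two gametes of individual ``i``.  Present iff ``phased``.
    meta : dict
        Free-form provenance (filter counts, simulation seed, ...).
    """

    markers: pd.DataFrame
    genotypes: np.ndarray
    samples: list[str]
    populations: np.ndarray
    phased: bool = False
    haplotypes: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.markers = _as_marker_frame(self.markers)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.populations = np.asarray(self.populations, dtype=object)
        n_ind, n_mark = self.genotypes.shape
        if len(self.samples) != n_ind:
            raise PanelError("sample list length does not match genotype rows")
        if len(self.populations) != n_ind:
            raise PanelError("population labels do not match genotype rows")
        if len(self.markers) != n_mark:
            raise PanelError("marker table length does not match genotype columns")
        if self.phased:
            if self.haplotypes is None:
                raise PanelError("phased panel requires a haplotype matrix")
            self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
            if self.haplotypes.shape != (2 * n_ind, n_mark):
                raise PanelError("haplotype matrix must be (2*n_individuals, n_markers)")

    # -- basic properties -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[1]

    @property
    def population_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p, None)
        return list(seen)

    def individuals_of(self, population: str) -> np.ndarray:
        """Row indices of the individuals belonging to ``population``."""
        idx = np.flatnonzero(self.populations == population)
        if idx.size == 0:
            raise PanelError(f"unknown population {population!r}")
        return idx

    def validate(self) -> None:
        """Check structural invariants; raise :class:`PanelError` on violation."""
        g = self.genotypes
        ok = (g == MISSING) | ((g >= 0) & (g <= 2))
        if not ok.all():
            raise PanelError("genotype dosages outside {0,1,2,missing}")
        m = self.markers
        if (m["pos"] < 1).any():
            raise PanelError("positions must be 1-based (>= 1)")
        if (m["ref"] == m["alt"]).any():
            raise PanelError("ref and alt alleles must differ")
        for chrom, sub in m.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if not (np.diff(pos) > 0).all():
                raise PanelError(f"markers on {chrom} not strictly increasing in position")
        if self.phased:
            h = self.haplotypes
            hs = h[0::2].astype(np.int16) + h[1::2].astype(np.int16)
            called = (h[0::2] != MISSING) & (h[1::2] != MISSING) & (g != MISSING)
            if not (hs[called] == g[called]).all():
                raise PanelError("haplotype sums disagree with dosages")

    # -- subsetting -------------------------------------------------------
    def take_markers(self, index: np.ndarray) -> "PopulationPanel":
        """Panel restricted to marker columns ``index`` (order preserved as given)."""
        index = np.asarray(index)
        return PopulationPanel(
            markers=self.markers.iloc[index].reset_index(drop=True),
            genotypes=self.genotypes[:, index],
            samples=list(self.samples),
            populations=self.populations.copy(),
            phased=self.phased,
            haplotypes=None if self.haplotypes is None else self.haplotypes[:, index],
            meta=dict(self.meta),
        )

    def take_samples(self, index: np.ndarray) -> "PopulationPanel":
        """Panel restricted to individuals ``index`` (gametes follow)."""
        index = np.asarray(index)
        hap_index = np.empty(2 * index.size, dtype=np.int64)
        hap_index[0::2] = 2 * index
        hap_index[1::2] = 2 * index + 1
        return PopulationPanel(
            markers=self.markers.copy(),
            genotypes=self.genotypes[index],
            samples=[self.samples[i] for i in index],
            populations=self.populations[index],
            phased=self.phased,
            haplotypes=None if self.haplotypes is None else self.haplotypes[hap_index],
            meta=dict(self.meta),
        )

    def to_haplotype_set(self) -> "HaplotypeSet":
        """Gametes x markers view of a phased panel."""
        if not self.phased or self.haplotypes is None:
            raise PanelError("haplotype extraction requires a phased panel")
        return HaplotypeSet(
            markers=self.markers.copy(),
            haplotypes=self.haplotypes.copy(),
            populations=np.repeat(self.populations, 2),
        )


@dataclass
class HaplotypeSet:
    """Gametes x markers binary matrix with a population label per gamete."""

    markers: pd.DataFrame
    haplotypes: np.ndarray
    populations: np.ndarray

    def __post_init__(self) -> None:
        self.markers = _as_marker_frame(self.markers)
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        self.populations = np.asarray(self.populations, dtype=object)
        if self.haplotypes.shape[0] != len(self.populations):
            raise PanelError("population labels do not match gamete rows")
        if self.haplotypes.shape[1] != len(self.markers):
            raise PanelError("marker table length does not match haplotype columns")
        ok = (self.haplotypes == MISSING) | (self.haplotypes == 0) | (self.haplotypes == 1)
        if not ok.all():
            raise PanelError("haplotype entries outside {0,1,missing}")

    @property
    def n_gametes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.haplotypes.shape[1]

    def take_gametes(self, index: np.ndarray) -> "HaplotypeSet":
        index = np.asarray(index)
        return HaplotypeSet(
            markers=self.markers.copy(),
            haplotypes=self.haplotypes[index],
            populations=self.populations[index],
        )

    def take_markers(self, index: np.ndarray) -> "HaplotypeSet":
        index = np.asarray(index)
        return HaplotypeSet(
            markers=self.markers.iloc[index].reset_index(drop=True),
            haplotypes=self.haplotypes[:, index],
            populations=self.populations.copy(),
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_popmap(popmap_path: str | Path) -> dict[str, str]:
    """Read a two-column TSV ``sample_id<TAB>population`` (header optional)."""
    popmap: dict[str, str] = {}
    with open(popmap_path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise PanelError(f"{popmap_path}:{line_no}: expected 2 tab-separated columns")
            if line_no == 1 and parts[0].lower() in {"sample", "sample_id"}:
                continue
            popmap[parts[0]] = parts[1]
    if not popmap:
        raise PanelError(f"empty population map {popmap_path}")
    return popmap


def read_panel(vcf_path: str | Path, popmap_path: str | Path) -> PopulationPanel:
    """Read a bi-allelic SNP VCF plus a sample->population map.

    The panel is flagged phased iff every genotype call in the file uses the
    phased separator ``|``.  Multi-allelic records raise an error naming the
    record; samples absent from the popmap raise an error naming the sample.
    """
    from cyvcf2 import VCF

    popmap = read_popmap(popmap_path)
    vcf = VCF(str(vcf_path), gts012=False)
    samples = list(vcf.samples)
    for s in samples:
        if s not in popmap:
            raise PanelError(f"sample {s!r} present in VCF but missing from popmap")

    rows = []
    dosage_cols: list[np.ndarray] = []
    hap_cols: list[np.ndarray] = []
    all_phased = True
    any_record = False
    for var in vcf:
        any_record = True
        if len(var.ALT) != 1:
            raise PanelError(
                f"multi-allelic record at {var.CHROM}:{var.POS} (alleles {var.REF},{','.join(var.ALT)})"
            )
        rows.append((var.CHROM, var.POS, var.ID or f"{var.CHROM}_{var.POS}", var.REF, var.ALT[0]))
        gt = np.array(var.genotypes, dtype=np.int64)  # (n, 3): a0, a1, phased
        a = gt[:, 0:2]
        phased_flags = gt[:, 2].astype(bool)
        called = (a >= 0).all(axis=1)
        dos = np.where(called, a.clip(min=0).sum(axis=1), MISSING).astype(np.int8)
        dosage_cols.append(dos)
        hap = np.where(a >= 0, a, MISSING).astype(np.int8)
        hap_cols.append(hap.reshape(-1))  # (2n,) gametes interleaved
        if not phased_flags[called].all():
            all_phased = False
    if not any_record:
        raise PanelError(f"no variant records in {vcf_path}")

    markers = pd.DataFrame(rows, columns=MARKER_COLUMNS)
    genotypes = np.column_stack(dosage_cols)
    haplotypes = np.column_stack(hap_cols) if all_phased else None

    order = np.lexsort((markers["pos"].to_numpy(), markers["chrom"].astype(str).to_numpy()))
    panel = PopulationPanel(
        markers=markers.iloc[order].reset_index(drop=True),
        genotypes=genotypes[:, order],
        samples=samples,
        populations=np.array([popmap[s] for s in samples], dtype=object),
        phased=all_phased,
        haplotypes=None if haplotypes is None else haplotypes[:, order],
    )
    return panel


def write_panel(panel: PopulationPanel, vcf_path: str | Path, popmap_path: str | Path) -> None:
    """Write a panel as an uncompressed VCF 4.2 (GT only) plus a popmap TSV."""
    sep = "|" if panel.phased else "/"
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=landracekit\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(panel.markers["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(panel.samples) + "\n")
        g = panel.genotypes
        h = panel.haplotypes
        for j, row in enumerate(panel.markers.itertuples(index=False)):
            fields = [str(row.chrom), str(row.pos), str(row.id), row.ref, row.alt, ".", "PASS", ".", "GT"]
            if panel.phased:
                a0, a1 = h[0::2, j], h[1::2, j]
            else:
                # unphased: expand dosages deterministically (0->0/0, 1->0/1, 2->1/1)
                a0 = np.where(g[:, j] == 2, 1, 0)
                a1 = np.where(g[:, j] >= 1, 1, 0)
            calls = []
            for i in range(panel.n_individuals):
                if g[i, j] == MISSING:
                    calls.append(f".{sep}.")
                else:
                    calls.append(f"{a0[i]}{sep}{a1[i]}")
            fh.write("\t".join(fields + calls) + "\n")
    with open(popmap_path, "w") as fh:
        fh.write("sample_id\tpopulation\n")
        for s, p in zip(panel.samples, panel.populations):
            fh.write(f"{s}\t{p}\n")


# ---------------------------------------------------------------------------
# Filtering and marker intersection
# ---------------------------------------------------------------------------

def filter_panel(
    panel: PopulationPanel,
    min_marker_call_rate: float = 0.9,
    min_sample_call_rate: float = 0.9,
    biallelic_only: bool = True,
) -> PopulationPanel:
    """Apply call-rate filters: markers first, then samples.

    Marker call rates are computed on the incoming matrix; sample call rates
    on the marker-filtered matrix.  Counts removed are recorded in
    ``panel.meta['filter']`` and logged.
    """
    for r in (min_marker_call_rate, min_sample_call_rate):
        if not 0 <= r <= 1:
            raise PanelError("call-rate thresholds must lie in [0, 1]")
    called = panel.genotypes != MISSING
    marker_rate = called.mean(axis=0)
    keep_markers = marker_rate >= min_marker_call_rate
    n_markers_removed = int((~keep_markers).sum())
    if keep_markers.sum() == 0:
        raise PanelError("no markers survive the call-rate filter")
    out = panel.take_markers(np.flatnonzero(keep_markers))

    sample_rate = (out.genotypes != MISSING).mean(axis=1)
    keep_samples = sample_rate >= min_sample_call_rate
    n_samples_removed = int((~keep_samples).sum())
    if keep_samples.sum() == 0:
        raise PanelError("no samples survive the call-rate filter")
    out = out.take_samples(np.flatnonzero(keep_samples))

    if biallelic_only:
        # dosage-coded input is bi-allelic by construction; the flag exists for
        # symmetry with upstream VCF filtering and forbids duplicate positions.
        dup = out.markers.duplicated(subset=["chrom", "pos"], keep=False)
        if dup.any():
            first = out.markers[dup].iloc[0]
            raise PanelError(f"duplicate marker position {first['chrom']}:{first['pos']} after filtering")
    out.meta["filter"] = {
        "markers_removed": n_markers_removed,
        "samples_removed": n_samples_removed,
        "min_marker_call_rate": min_marker_call_rate,
        "min_sample_call_rate": min_sample_call_rate,
    }
    logger.info(
        "filter_panel removed %d markers and %d samples", n_markers_removed, n_samples_removed
    )
    return out


def intersect_panels(
    a: PopulationPanel, b: PopulationPanel
) -> tuple[PopulationPanel, PopulationPanel]:
    """Restrict two panels to markers shared by (chrom, pos) with compatible alleles.

    A marker matches when the (ref, alt) pairs are equal, or swapped — in the
    swapped case dosages in ``b`` are recoded ``d -> 2 - d`` (haplotype alleles
    flipped) so that the alt allele orientation agrees with ``a``.  Markers at a
    shared position with an incompatible allele pair are dropped and logged.
    """
    am = a.markers.assign(_ia=np.arange(len(a.markers)))
    bm = b.markers.assign(_ib=np.arange(len(b.markers)))
    merged = am.merge(bm, on=["chrom", "pos"], suffixes=("_a", "_b"))
    same = (merged["ref_a"] == merged["ref_b"]) & (merged["alt_a"] == merged["alt_b"])
    swapped = (merged["ref_a"] == merged["alt_b"]) & (merged["alt_a"] == merged["ref_b"])
    compatible = same | swapped
    n_dropped = int((~compatible).sum())
    if n_dropped:
        logger.warning("intersect_panels dropped %d allele-incompatible shared markers", n_dropped)
    merged = merged[compatible]
    if merged.empty:
        raise PanelError("empty intersection: no shared markers with compatible alleles")

    ia = merged["_ia"].to_numpy()
    ib = merged["_ib"].to_numpy()
    out_a = a.take_markers(ia)
    out_b = b.take_markers(ib)
    swap_mask = swapped[compatible].to_numpy()
    if swap_mask.any():
        g = out_b.genotypes
        cols = np.flatnonzero(swap_mask)
        for j in cols:
            miss = g[:, j] == MISSING
            g[:, j] = 2 - g[:, j]
            g[miss, j] = MISSING
        if out_b.haplotypes is not None:
            h = out_b.haplotypes
            for j in cols:
                miss = h[:, j] == MISSING
                h[:, j] = 1 - h[:, j]
                h[miss, j] = MISSING
        # adopt a's allele orientation in the marker table
        mb = out_b.markers
        mb.loc[swap_mask, ["ref", "alt"]] = out_a.markers.loc[swap_mask, ["ref", "alt"]].to_numpy()
    out_a.meta["intersection"] = out_b.meta["intersection"] = {
        "n_shared": len(merged),
        "n_allele_incompatible_dropped": n_dropped,
        "n_swapped": int(swap_mask.sum()),
    }
    return out_a, out_b


# ---------------------------------------------------------------------------
# Sampling designs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Within:
    """Draw ``n`` individuals without replacement from one population."""

    population: str
    n: int


@dataclass(frozen=True)
class Across:
    """Draw ``n`` distinct populations, then one individual from each."""

    n: int


def sample_individuals(
    panel: PopulationPanel, design: Within | Across, seed: int | np.random.Generator
) -> PopulationPanel:
    """Subsample individuals according to a within- or across-population design."""
    rng = np.random.default_rng(seed)
    if isinstance(design, Within):
        idx = panel.individuals_of(design.population)
        if design.n > idx.size:
            raise PanelError(
                f"population {design.population!r} has {idx.size} individuals, cannot draw {design.n}"
            )
        chosen = np.sort(rng.choice(idx, size=design.n, replace=False))
    elif isinstance(design, Across):
        pops = panel.population_labels
        if design.n > len(pops):
            raise PanelError(f"panel has {len(pops)} populations, cannot draw {design.n}")
        chosen_pops = rng.choice(np.array(pops, dtype=object), size=design.n, replace=False)
        chosen = np.sort(
            np.array([rng.choice(panel.individuals_of(p)) for p in chosen_pops], dtype=np.int64)
        )
    else:  # pragma: no cover - defensive
        raise TypeError(f"unknown design {design!r}")
    return panel.take_samples(chosen)
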