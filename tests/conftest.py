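"""Shared fixtures: tiny hand-built panels and session-scoped simulations."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from landracekit import (
    PopulationPanel,
    SimulationConfig,
    phase_pair_config,
    simulate_panel,
    single_landrace_config,
)
from landracekit.panel import MARKER_COLUMNS


def make_markers(positions, chrom="1", ref="A", alt="G"):
    """Marker table at the given positions on one chromosome."""
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": list(positions),
            "id": [f"m{p}" for p in positions],
            "ref": ref,
            "alt": alt,
        },
        columns=MARKER_COLUMNS,
    )


def make_panel(genotypes, populations, positions=None, phased=False, haplotypes=None, chrom="1"):
    """Panel from a plain dosage matrix; positions default to 1, 2, 3..."""
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n, m = genotypes.shape
    if positions is None:
        positions = range(1, m + 1)
    return PopulationPanel(
        markers=make_markers(positions, chrom=chrom),
        genotypes=genotypes,
        samples=[f"S{i}" for i in range(n)],
        populations=np.asarray(populations, dtype=object),
        phased=phased,
        haplotypes=haplotypes,
    )


def make_phased_panel(haplotypes, populations, positions=None, chrom="1"):
    """Phased panel from a gametes x markers matrix (rows 2i, 2i+1 pair up)."""
    haplotypes = np.asarray(haplotypes, dtype=np.int8)
    g = np.where(
        (haplotypes[0::2] == -1) | (haplotypes[1::2] == -1),
        -1,
        haplotypes[0::2] + haplotypes[1::2],
    ).astype(np.int8)
    panel = make_panel(g, populations, positions=positions, chrom=chrom)
    return PopulationPanel(
        markers=panel.markers,
        genotypes=g,
        samples=panel.samples,
        populations=panel.populations,
        phased=True,
        haplotypes=haplotypes,
    )


@pytest.fixture(scope="session")
def default_panel():
    """Ten diverged populations at the calibrated drift regime."""
    panel, truth = simulate_panel(SimulationConfig(seed=42))
    return panel, truth


@pytest.fixture(scope="session")
def landrace_panel():
    """Single deep-LD population of 48 individuals."""
    panel, truth = simulate_panel(single_landrace_config(seed=42))
    return panel, truth


@pytest.fixture(scope="session")
def phase_panel():
    """Two populations sharing ancestral LD."""
    panel, truth = simulate_panel(phase_pair_config(seed=42))
    return panel, truth
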