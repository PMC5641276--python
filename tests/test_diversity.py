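"""Diversity statistics against hand-worked and pairwise-counting oracles."""

import itertools

import numpy as np
import pytest

from landracekit import (
    WindowSpec,
    diversity_summary,
    fis,
    haplotype_heterozygosity,
    nucleotide_diversity,
    proportion_polymorphic,
)
from landracekit.panel import MISSING, PanelError

from conftest import make_panel, make_phased_panel


class TestProportionPolymorphic:
    def test_hand_counted(self):
        g = np.array(
            [
                [0, 2, 1, 0],
                [0, 2, 2, MISSING],
                [0, 2, 0, 0],
            ],
            dtype=np.int8,
        )
        # markers 0, 1: fixed; marker 2: polymorphic; marker 3: fixed among calls
        panel = make_panel(g, ["P"] * 3)
        assert proportion_polymorphic(panel) == pytest.approx(0.25)

    def test_het_only_marker_is_polymorphic(self):
        panel = make_panel(np.array([[1], [1]], np.int8), ["P", "P"])
        assert proportion_polymorphic(panel) == 1.0


class TestNucleotideDiversity:
    def test_matches_pairwise_gamete_oracle(self):
        # pi per marker must equal the mean over all unordered pairs of
        # callable gametes of the indicator "alleles differ"
        rng = np.random.default_rng(0)
        g = rng.integers(0, 3, (15, 100)).astype(np.int8)
        g[rng.random((15, 100)) < 0.1] = MISSING
        panel = make_panel(g, ["P"] * 15)
        pi, _ = nucleotide_diversity(panel)

        for j in range(100):
            gametes = []
            for d in g[:, j]:
                if d != MISSING:
                    gametes += [1, 0] if d == 1 else [d // 2, d // 2]
            diffs = [a != b for a, b in itertools.combinations(gametes, 2)]
            np.testing.assert_allclose(pi[j], np.mean(diffs), atol=1e-12)

    def test_known_value(self):
        # k = 4 gametes, p = 1/4: pi = (4/3) * 2 * (1/4)(3/4) = 1/2
        panel = make_panel(np.array([[1], [0]], np.int8), ["P", "P"])
        pi, mean = nucleotide_diversity(panel)
        assert pi[0] == pytest.approx(0.5)
        assert mean == pytest.approx(0.5)

    def test_monomorphic_zero(self):
        panel = make_panel(np.full((5, 3), 2, np.int8), ["P"] * 5)
        pi, mean = nucleotide_diversity(panel)
        np.testing.assert_allclose(pi, 0.0)
        assert mean == 0.0

    def test_all_uncallable_errors(self):
        panel = make_panel(np.full((3, 2), MISSING, np.int8), ["P"] * 3)
        with pytest.raises(PanelError):
            nucleotide_diversity(panel)


class TestHaplotypeHeterozygosity:
    def test_hand_worked_window(self):
        # 4 gametes over 5 SNPs inside one 100-kb window; classes:
        # two identical gametes + two distinct -> x = (1/2, 1/4, 1/4)
        # H = (4/3)(1 - (1/4 + 1/16 + 1/16)) = (4/3)(5/8) = 5/6
        haps = np.array(
            [
                [0, 0, 0, 0, 0],
                [0, 0, 0, 0, 0],
                [1, 1, 1, 1, 1],
                [0, 1, 0, 1, 0],
            ],
            dtype=np.int8,
        )
        panel = make_phased_panel(haps, ["A", "B"], positions=[100, 200, 300, 400, 500])
        vals, mean = haplotype_heterozygosity(panel.to_haplotype_set())
        # every anchored window with >= 5 SNPs is the full block here
        assert vals[0] == pytest.approx(5 / 6)
        assert mean == pytest.approx(vals.mean())

    def test_incomplete_gametes_excluded(self):
        haps = np.array(
            [
                [0, 0, 0, 0, 0],
                [1, 1, 1, 1, 1],
                [MISSING, 1, 1, 1, 1],
                [0, 1, 0, 1, 0],
            ],
            dtype=np.int8,
        )
        panel = make_phased_panel(haps, ["A", "B"], positions=[1, 2, 3, 4, 5])
        vals, _ = haplotype_heterozygosity(panel.to_haplotype_set())
        # 3 complete gametes, all distinct: H = (3/2)(1 - 3/9) = 1
        assert vals[0] == pytest.approx(1.0)

    def test_min_snps_respected(self):
        haps = np.zeros((4, 4), dtype=np.int8)
        panel = make_phased_panel(haps, ["A", "B"], positions=[1, 2, 3, 4])
        with pytest.raises(PanelError):
            haplotype_heterozygosity(panel.to_haplotype_set(), WindowSpec(100_000, 5))
        vals, _ = haplotype_heterozygosity(panel.to_haplotype_set(), WindowSpec(100_000, 4))
        assert len(vals) == 1

    def test_window_width_anchoring(self):
        # SNPs at 0..4 and a distant cluster; narrow windows never span both
        pos = [0, 10, 20, 30, 40, 900_000, 900_010, 900_020, 900_030, 900_040]
        haps = np.zeros((4, 10), dtype=np.int8)
        panel = make_phased_panel(haps, ["A", "B"], positions=pos)
        vals, _ = haplotype_heterozygosity(panel.to_haplotype_set(), WindowSpec(1000, 5))
        assert len(vals) == 2  # one full window per cluster

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            WindowSpec(0, 5)
        with pytest.raises(ValueError):
            WindowSpec(100, 1)


class TestFis:
    def test_all_heterozygotes_is_minus_one(self):
        # h = 1, p = 1/2: b = (n/(n-1))(1/4 - (2n-1)/(4n)) < 0, c = 1/2
        # With many such loci f -> 1 - c/(b+c); analytically for n = 10:
        # b = (10/9)(0.25 - 19/40) = -0.25, c = 0.5 -> f = 1 - 0.5/0.25 = -1
        g = np.ones((10, 20), dtype=np.int8)
        panel = make_panel(g, ["P"] * 10)
        f, p = fis(panel, n_perms=200, seed=0)
        assert f == pytest.approx(-1.0)
        assert p < 0.05

    def test_no_heterozygotes_is_plus_one(self):
        rng = np.random.default_rng(1)
        g = 2 * rng.integers(0, 2, (10, 20)).astype(np.int8)
        panel = make_panel(g, ["P"] * 10)
        f, p = fis(panel, n_perms=200, seed=0)
        assert f == pytest.approx(1.0)
        assert p < 0.05

    def test_hwe_panel_near_zero_and_nonsignificant(self):
        rng = np.random.default_rng(2)
        p_freq = rng.uniform(0.2, 0.8, 300)
        g = (rng.random((40, 300)) < p_freq).astype(np.int8) + (
            rng.random((40, 300)) < p_freq
        ).astype(np.int8)
        panel = make_panel(g, ["P"] * 40)
        f, p = fis(panel, n_perms=300, seed=3)
        assert abs(f) < 0.05
        assert p > 0.05

    def test_monomorphic_errors(self):
        panel = make_panel(np.zeros((5, 4), np.int8), ["P"] * 5)
        with pytest.raises(PanelError):
            fis(panel)

    def test_seed_reproducible(self):
        rng = np.random.default_rng(4)
        g = rng.integers(0, 3, (15, 40)).astype(np.int8)
        panel = make_panel(g, ["P"] * 15)
        assert fis(panel, 100, seed=9) == fis(panel, 100, seed=9)


def test_diversity_summary_consistent(landrace_panel):
    panel, _ = landrace_panel
    s = diversity_summary(panel, n_perms=100, seed=0)
    assert s.PP == pytest.approx(proportion_polymorphic(panel))
    assert 0 < s.pi_mean < 0.5
    assert s.H_mean is not None and 0 < s.H_mean <= 1
    assert s.n_windows > 0
    assert s.Fis is not None and abs(s.Fis) < 0.2  # random mating in the model
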