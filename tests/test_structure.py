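"""Structure analyses validated against independent library oracles
(scikit-bio, dendropy) and hand-worked cases."""

import io

import dendropy
import numpy as np
import pytest
import skbio
from skbio.tree import nj as skbio_nj

from landracekit import (
    Coordinates,
    DistanceMatrix,
    ld_prune,
    mantel,
    mrd,
    neighbor_joining,
    pcoa,
    procrustes_fit,
)
from landracekit.panel import MISSING, PanelError

from conftest import make_panel, make_phased_panel


def random_distance(n, seed, labels=None):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n, 4))
    d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
    return DistanceMatrix(labels or [f"t{i}" for i in range(n)], d)


class TestMRD:
    def test_hand_cases(self):
        # identical -> 0; opposite homozygotes -> 1; het vs hom -> 0.5
        g = np.array([[0, 0], [0, 0], [2, 2], [1, 0]], dtype=np.int8)
        dm = mrd(make_panel(g, ["P"] * 4))
        assert dm.values[0, 1] == pytest.approx(0.0)
        assert dm.values[0, 2] == pytest.approx(1.0)
        # ind 3 vs ind 0: freq diffs (0.5, 0) -> sqrt((0.25)/2) = sqrt(1/8)
        assert dm.values[0, 3] == pytest.approx(np.sqrt(1 / 8))

    def test_matches_per_pair_loop_with_missing(self):
        rng = np.random.default_rng(1)
        g = rng.integers(0, 3, (10, 40)).astype(np.int8)
        g[rng.random((10, 40)) < 0.2] = MISSING
        dm = mrd(make_panel(g, ["P"] * 10))
        for i in range(10):
            for j in range(i + 1, 10):
                ok = (g[i] != MISSING) & (g[j] != MISSING)
                diff = (g[i, ok] / 2.0) - (g[j, ok] / 2.0)
                expected = np.sqrt((diff**2).mean())
                np.testing.assert_allclose(dm.values[i, j], expected, atol=1e-12)

    def test_no_shared_markers_errors(self):
        g = np.array([[0, MISSING], [MISSING, 0]], dtype=np.int8)
        with pytest.raises(PanelError, match="share no called markers"):
            mrd(make_panel(g, ["P", "P"]))

    def test_validation_rejects_asymmetry(self):
        with pytest.raises(PanelError, match="symmetric"):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(PanelError, match="diagonal"):
            DistanceMatrix(["a", "b"], np.array([[1.0, 1.0], [1.0, 0.0]]))


class TestNeighborJoining:
    def test_wikipedia_example_branch_lengths(self):
        # classical 5-taxon additive matrix; NJ recovers exact branch lengths
        d = np.array(
            [
                [0, 5, 9, 9, 8],
                [5, 0, 10, 10, 9],
                [9, 10, 0, 8, 7],
                [9, 10, 8, 0, 3],
                [8, 9, 7, 3, 0],
            ],
            dtype=float,
        )
        labels = ["a", "b", "c", "d", "e"]
        newick = neighbor_joining(DistanceMatrix(labels, d))
        tree = dendropy.Tree.get(data=newick, schema="newick")
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        for i, li in enumerate(labels):
            for j, lj in enumerate(labels):
                if i < j:
                    assert pdm.distance(taxa[li], taxa[lj]) == pytest.approx(d[i, j])

    def test_topology_matches_skbio(self):
        dm = random_distance(8, seed=2)
        ours = neighbor_joining(dm)
        theirs = skbio_nj(skbio.DistanceMatrix(dm.values, ids=dm.labels))
        tns = dendropy.TaxonNamespace()
        t1 = dendropy.Tree.get(data=ours, schema="newick", taxon_namespace=tns)
        t2 = dendropy.Tree.get(
            data=str(theirs).strip(), schema="newick", taxon_namespace=tns
        )
        t1.encode_bipartitions()
        t2.encode_bipartitions()
        rf = dendropy.calculate.treecompare.symmetric_difference(t1, t2)
        assert rf == 0

    def test_deterministic(self):
        dm = random_distance(6, seed=3)
        assert neighbor_joining(dm) == neighbor_joining(dm)

    def test_too_few_taxa_errors(self):
        with pytest.raises(PanelError):
            neighbor_joining(random_distance(2, seed=0))


class TestPcoa:
    def test_recovers_euclidean_configuration(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(10, 3))
        x -= x.mean(axis=0)
        d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        coords = pcoa(DistanceMatrix([f"t{i}" for i in range(10)], d), k=3)
        # inter-point distances reproduced exactly in 3 axes
        y = coords.axes
        d2 = np.sqrt(((y[:, None] - y[None]) ** 2).sum(-1))
        np.testing.assert_allclose(d2, d, atol=1e-8)
        # eigenvalues beyond rank 3 vanish
        assert np.abs(coords.eigenvalues[3:]).max() < 1e-8

    def test_matches_skbio_eigenvalues(self):
        dm = random_distance(9, seed=5)
        ours = pcoa(dm)
        theirs = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(dm.values, ids=dm.labels), method="eigh"
        )
        np.testing.assert_allclose(
            ours.eigenvalues[:4], theirs.eigvals.to_numpy()[:4], atol=1e-8
        )
        # axes agree up to sign
        for a in range(3):
            ratio = ours.axes[:, a] / theirs.samples.to_numpy()[:, a]
            np.testing.assert_allclose(np.abs(ratio), 1.0, atol=1e-6)

    def test_k_bounds(self):
        dm = random_distance(5, seed=6)
        with pytest.raises(PanelError):
            pcoa(dm, k=5)


class TestMantel:
    def test_statistic_matches_skbio(self):
        d1 = random_distance(12, seed=7)
        d2 = random_distance(12, seed=8, labels=d1.labels)
        r, _ = mantel(d1, d2, n_perms=99, seed=0)
        r_skbio, _, _ = skbio.stats.distance.mantel(
            skbio.DistanceMatrix(d1.values, ids=d1.labels),
            skbio.DistanceMatrix(d2.values, ids=d2.labels),
            permutations=0,
        )
        assert r == pytest.approx(float(r_skbio), abs=1e-12)

    def test_self_comparison_significant(self):
        d1 = random_distance(12, seed=9)
        r, p = mantel(d1, d1, n_perms=199, seed=1)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1 / 200)

    def test_label_mismatch_errors(self):
        d1 = random_distance(5, seed=10)
        d2 = random_distance(5, seed=11)
        d2.labels = list(reversed(d1.labels))
        with pytest.raises(PanelError):
            mantel(d1, d2)


class TestProcrustes:
    def test_rotation_and_reflection_invariant(self):
        rng = np.random.default_rng(12)
        a = rng.normal(size=(10, 3))
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))  # random orthogonal (may reflect)
        b = (a @ q) * 2.5 + rng.normal(size=3)
        labels = [f"t{i}" for i in range(10)]
        c1 = Coordinates(labels, a, np.ones(3))
        c2 = Coordinates(labels, b, np.ones(3))
        assert procrustes_fit(c1, c2, k=3) == pytest.approx(1.0, abs=1e-10)

    def test_unrelated_lower_than_related(self):
        rng = np.random.default_rng(13)
        a = rng.normal(size=(20, 3))
        noise = a + 0.3 * rng.normal(size=(20, 3))
        unrelated = rng.normal(size=(20, 3))
        labels = [f"t{i}" for i in range(20)]
        fit_noise = procrustes_fit(
            Coordinates(labels, a, np.ones(3)), Coordinates(labels, noise, np.ones(3))
        )
        fit_unrel = procrustes_fit(
            Coordinates(labels, a, np.ones(3)), Coordinates(labels, unrelated, np.ones(3))
        )
        assert fit_noise > 0.9 > fit_unrel

    def test_insufficient_axes_errors(self):
        labels = ["a", "b", "c"]
        c = Coordinates(labels, np.random.default_rng(0).normal(size=(3, 2)), np.ones(2))
        with pytest.raises(PanelError):
            procrustes_fit(c, c, k=3)


class TestLdPrune:
    def test_duplicate_markers_collapse(self):
        rng = np.random.default_rng(14)
        base = rng.integers(0, 2, (40, 1)).astype(np.int8)
        haps = np.repeat(base, 5, axis=1)  # 5 perfectly correlated copies
        panel = make_phased_panel(haps, ["P"] * 20)
        pruned = ld_prune(panel.to_haplotype_set(), window_snps=5, step_snps=1)
        assert pruned.n_markers == 1
        # tie-break keeps the earliest position
        assert pruned.markers["pos"].iloc[0] == 1

    def test_independent_markers_untouched(self):
        rng = np.random.default_rng(15)
        haps = rng.integers(0, 2, (60, 30)).astype(np.int8)
        panel = make_phased_panel(haps, ["P"] * 30)
        hs = panel.to_haplotype_set()
        pruned = ld_prune(hs, window_snps=10, step_snps=2, r2_threshold=0.99)
        assert pruned.n_markers == 30

    def test_lower_maf_member_removed(self):
        # common: 40/80 alt gametes; rare: the same minus 4 -> MAF 0.45,
        # correlation r^2 = (0.225 / (0.5 * sqrt(0.45 * 0.55)))^2 ~ 0.82 > 0.8
        common = np.array([1] * 40 + [0] * 40, dtype=np.int8)
        rare = common.copy()
        rare[:4] = 0
        haps = np.column_stack([common, rare])
        assert np.corrcoef(common, rare)[0, 1] ** 2 > 0.8
        panel = make_phased_panel(haps, ["P"] * 40)
        pruned = ld_prune(panel.to_haplotype_set(), window_snps=2, step_snps=1)
        assert pruned.n_markers == 1
        assert pruned.markers["pos"].iloc[0] == 1  # the common marker survives
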