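"""LD statistics against brute-force counting oracles and the analytic
properties of the drift-recombination decay curve."""

import numpy as np
import pandas as pd
import pytest

from landracekit import (
    DecayFit,
    decay_distance,
    expected_r2,
    hill_weir_fit,
    interchromosomal_comparison,
    interchromosomal_ld,
    pairwise_ld,
    sample_size_ld,
    sampling_scheme_ld,
)
from landracekit.ld import r_matrix
from landracekit.panel import MISSING, PanelError

from conftest import make_phased_panel


def brute_r(col_a, col_b):
    """Signed gametic correlation over gametes called at both markers."""
    ok = (col_a != MISSING) & (col_b != MISSING)
    a, b = col_a[ok].astype(float), col_b[ok].astype(float)
    pa, pb, pab = a.mean(), b.mean(), (a * b).mean()
    denom = np.sqrt(pa * (1 - pa) * pb * (1 - pb))
    if denom == 0:
        return np.nan
    return (pab - pa * pb) / denom


class TestRMatrix:
    def test_matches_brute_force_with_missing(self):
        rng = np.random.default_rng(0)
        H = rng.integers(0, 2, (30, 25)).astype(np.int8)
        H[rng.random((30, 25)) < 0.15] = MISSING
        r, n = r_matrix(H)
        for i in range(25):
            for j in range(25):
                expected = brute_r(H[:, i], H[:, j])
                if np.isnan(expected):
                    assert np.isnan(r[i, j])
                else:
                    np.testing.assert_allclose(r[i, j], expected, atol=1e-12)
                shared = ((H[:, i] != MISSING) & (H[:, j] != MISSING)).sum()
                assert n[i, j] == shared

    def test_perfect_coupling_and_repulsion(self):
        x = np.array([0, 0, 1, 1, 0, 1], dtype=np.int8)
        H = np.column_stack([x, x, 1 - x])
        r, _ = r_matrix(H)
        assert r[0, 1] == pytest.approx(1.0)
        assert r[0, 2] == pytest.approx(-1.0)

    def test_min_gametes_masks(self):
        H = np.array([[0, MISSING], [1, MISSING], [MISSING, 0], [MISSING, 1]], dtype=np.int8)
        r, _ = r_matrix(H, min_gametes=2)
        assert np.isnan(r[0, 1])


class TestPairwiseLd:
    def test_distances_and_filter(self):
        rng = np.random.default_rng(1)
        H = rng.integers(0, 2, (40, 4)).astype(np.int8)
        panel = make_phased_panel(H, ["P"] * 20, positions=[100, 500, 2000, 10_000])
        table = pairwise_ld(panel.to_haplotype_set(), max_dist_bp=1900)
        got = set(map(tuple, table[["marker_i", "marker_j"]].to_numpy()))
        assert ("m100", "m500") in got
        assert ("m500", "m2000") in got
        assert ("m100", "m10000") not in got
        row = table[(table.marker_i == "m100") & (table.marker_j == "m500")].iloc[0]
        assert row.distance_bp == 400
        np.testing.assert_allclose(row.r2, row.r**2, atol=1e-15)
        np.testing.assert_allclose(row.r, brute_r(H[:, 0], H[:, 1]), atol=1e-12)

    def test_monomorphic_pairs_skipped(self):
        H = np.column_stack(
            [np.array([0, 1] * 10, np.int8), np.zeros(20, np.int8)]
        )
        panel = make_phased_panel(H, ["P"] * 10, positions=[10, 20])
        table = pairwise_ld(panel.to_haplotype_set())
        assert len(table) == 0

    def test_cross_chromosome_pairs_excluded(self):
        rng = np.random.default_rng(2)
        H = rng.integers(0, 2, (40, 2)).astype(np.int8)
        import pandas as pd
        from conftest import make_markers
        from landracekit import PopulationPanel

        m1 = make_markers([100], chrom="1")
        m2 = make_markers([150], chrom="2")
        markers = pd.concat([m1, m2], ignore_index=True)
        markers["id"] = ["a", "b"]
        panel = make_phased_panel(H, ["P"] * 20)
        panel.markers[:] = markers
        table = pairwise_ld(panel.to_haplotype_set())
        assert len(table) == 0


class TestExpectedR2:
    def test_value_at_zero(self):
        # C = 0: (10/22) * (1 + 36/(22 n))
        for n in (4, 48, 96):
            assert expected_r2(0.0, n) == pytest.approx((10 / 22) * (1 + 36 / (22 * n)))

    def test_asymptote_is_one_over_n(self):
        assert expected_r2(1e9, 96) == pytest.approx(1 / 96, rel=1e-4)

    def test_monotone_decreasing(self):
        C = np.logspace(-3, 6, 200)
        vals = expected_r2(C, 50)
        assert (np.diff(vals) < 0).all()


class TestHillWeirFit:
    @pytest.mark.parametrize("rho", [1e-6, 1e-4])
    def test_recovers_known_rho_from_noisy_curve(self, rho):
        rng = np.random.default_rng(3)
        n = 96
        d = rng.uniform(100, 500_000, 4000)
        y = expected_r2(rho * d, n) + rng.normal(0, 0.02, d.size)
        fit = hill_weir_fit(pd.DataFrame({"distance_bp": d, "r2": y}), n_gametes=n)
        assert fit.rho_per_bp == pytest.approx(rho, rel=0.05)
        assert fit.n_pairs == 4000

    def test_predict_matches_expected(self):
        fit = DecayFit(rho_per_bp=1e-5, n_gametes=48, rss=0.0, n_pairs=100)
        d = np.array([0.0, 1e4, 1e6])
        np.testing.assert_allclose(fit.predict(d), expected_r2(1e-5 * d, 48), atol=1e-15)

    def test_too_few_or_degenerate_pairs_error(self):
        df = pd.DataFrame({"distance_bp": [100.0] * 10, "r2": [0.3] * 10})
        with pytest.raises(PanelError, match=">= 50"):
            hill_weir_fit(df, 96)
        df2 = pd.DataFrame({"distance_bp": [100.0] * 60, "r2": [0.3] * 60})
        with pytest.raises(PanelError, match="single distance"):
            hill_weir_fit(df2, 96)


class TestDecayDistance:
    def test_root_satisfies_threshold(self):
        fit = DecayFit(rho_per_bp=1e-5, n_gametes=96, rss=0.0, n_pairs=100)
        dd = decay_distance(fit, threshold=0.2)
        assert dd.status == "ok"
        assert fit.predict(dd.distance_bp) == pytest.approx(0.2, abs=1e-6)

    def test_below_threshold_at_origin(self):
        fit = DecayFit(rho_per_bp=1e-5, n_gametes=96, rss=0.0, n_pairs=100)
        dd = decay_distance(fit, threshold=0.5)  # curve starts at ~0.462
        assert dd.status == "below_threshold"
        assert dd.distance_bp == 0.0

    def test_small_sample_never_reaches(self):
        # n = 4 gametes: asymptote 1/4 > 0.2
        fit = DecayFit(rho_per_bp=1e-5, n_gametes=4, rss=0.0, n_pairs=100)
        dd = decay_distance(fit, threshold=0.2)
        assert dd.status == "not_reached"
        assert not dd.reached


class TestSamplingExperiments:
    def test_grid_shape_and_small_cells_skipped(self, default_panel):
        panel, _ = default_panel
        grid = sampling_scheme_ld(
            panel, l_values=[1, 4], g_values=[4, 20], repeats=2, seed=0
        )
        assert grid.mean_decay_bp.shape == (2, 2)
        assert np.isnan(grid.mean_decay_bp[0, 0])  # g*l = 4 < 12
        assert grid.n_ok[0, 0] == 0
        assert np.isfinite(grid.mean_decay_bp[1, 0])  # g*l = 20

    def test_sample_size_sorted_and_bounds(self, landrace_panel):
        panel, _ = landrace_panel
        df = sample_size_ld(panel, "P1", sizes=[20, 10], repeats=2, seed=0)
        assert df["size"].tolist() == [10, 20]
        assert (df["n_estimates"] > 0).all()
        with pytest.raises(PanelError):
            sample_size_ld(panel, "P1", sizes=[500], repeats=1)

    def test_interchromosomal_validation(self, default_panel):
        panel, _ = default_panel
        with pytest.raises(PanelError, match="must divide"):
            interchromosomal_ld(panel, l=5, n_individuals=24)
        with pytest.raises(PanelError):
            interchromosomal_ld(panel, l=11, n_individuals=22)

    def test_interchromosomal_fractions_valid(self, default_panel):
        panel, _ = default_panel
        frac = interchromosomal_ld(
            panel, l=4, n_individuals=8, maf_bin_width=0.1,
            snps_per_bin_per_chrom=10, repeats=3, seed=1,
        )
        assert frac.shape == (3,)
        assert ((frac >= 0) & (frac <= 1)).all()

    def test_comparison_requires_baseline(self, default_panel):
        panel, _ = default_panel
        with pytest.raises(PanelError, match="baseline"):
            interchromosomal_comparison(panel, l_values=[2, 4])

    def test_comparison_tables(self, default_panel):
        panel, _ = default_panel
        frac_df, tests = interchromosomal_comparison(
            panel,
            l_values=[1, 4],
            repeats=4,
            seed=2,
            n_individuals=8,
            maf_bin_width=0.1,
            snps_per_bin_per_chrom=10,
        )
        assert set(frac_df["l"]) == {1, 4}
        assert len(frac_df) == 8
        assert tests["l"].tolist() == [4]
        assert 0 <= tests["p_bonferroni"].iloc[0] <= 1
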