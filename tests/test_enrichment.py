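"""QTL-region vs background contrasts: chi-square, assignment, distances."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from radqtl.cross import LinkageMap
from radqtl.enrichment import (
    ContingencyTable2x2,
    IntervalSet,
    TEProfile,
    assign_inside,
    chisq_2x2,
    compare_distributions,
    map_to_physical,
    te_change_contrast,
    te_distance_matrix,
    te_profiles_from_table,
)
from radqtl.simulate import (
    CoalescentConfig,
    simulate_annotations,
    simulate_neutral_windows,
    simulate_te_profiles,
)
from radqtl.windows import SiteMatrix, window_stats


class TestChiSquare2x2:
    def test_near_balanced_selected_gene_table(self):
        """Counts (32, 101) vs (34, 101) give p = 0.83 to two decimals —
        an uncorrected Pearson test on an almost perfectly balanced table."""
        chi2, dof, p = chisq_2x2(ContingencyTable2x2(32, 101, 34, 101))
        assert dof == 1
        assert round(p, 2) == 0.83

    def test_identical_rows_give_zero_statistic(self):
        chi2, _, p = chisq_2x2(ContingencyTable2x2(10, 90, 10, 90))
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_diagonal_table_hand_computed(self):
        # [[10, 0], [0, 10]]: chi2 = n = 20, p = sf(20, 1)
        chi2, _, p = chisq_2x2(ContingencyTable2x2(10, 0, 0, 10))
        assert chi2 == pytest.approx(20.0, abs=1e-10)
        assert p == pytest.approx(stats.chi2.sf(20.0, 1), rel=1e-10)

    def test_no_continuity_correction(self, rng):
        """The statistic equals the raw Pearson formula
        n (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)) on random tables."""
        for _ in range(20):
            a, b, c, d = rng.integers(1, 200, size=4)
            chi2, _, _ = chisq_2x2(ContingencyTable2x2(int(a), int(b), int(c), int(d)))
            n = a + b + c + d
            expected = n * (a * d - b * c) ** 2 / (
                (a + b) * (c + d) * (a + c) * (b + d)
            )
            assert chi2 == pytest.approx(expected, rel=1e-10)

    def test_degenerate_marginals_rejected(self):
        with pytest.raises(ValueError, match="degenerate_table"):
            chisq_2x2(ContingencyTable2x2(0, 0, 5, 5))
        with pytest.raises(ValueError, match="degenerate_table"):
            chisq_2x2(ContingencyTable2x2(0, 5, 0, 5))
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 2, 3, 4)


class TestMapToPhysical:
    def _map(self):
        return LinkageMap(
            pd.DataFrame(
                {
                    "marker": ["a", "b", "c"],
                    "lg": ["1", "1", "1"],
                    "pos_cM": [0.0, 10.0, 30.0],
                    "pos_bp": [1_000, 11_000, 51_000],
                }
            )
        )

    def test_linear_interpolation(self):
        lmap = self._map()
        assert map_to_physical((0.0, 10.0), lmap, "1") == (1_000, 11_000)
        # 2.5 and 7.5 cM sit 25% / 75% along the 0-10 cM, 1000-11000 bp span
        assert map_to_physical((2.5, 7.5), lmap, "1") == (3_500, 8_500)
        # second segment has a different cM/bp slope
        assert map_to_physical((10.0, 20.0), lmap, "1") == (11_000, 31_000)

    def test_clipping_beyond_terminal_markers(self):
        lmap = self._map()
        assert map_to_physical((-5.0, 40.0), lmap, "1") == (1_000, 51_000)

    def test_errors(self):
        lmap = self._map()
        with pytest.raises(ValueError, match="out of order"):
            map_to_physical((5.0, 2.0), lmap, "1")
        with pytest.raises(ValueError, match="fewer than two"):
            map_to_physical((0.0, 1.0), lmap, "2")
        bare = LinkageMap(
            pd.DataFrame({"marker": ["a", "b"], "lg": ["1", "1"],
                          "pos_cM": [0.0, 5.0]})
        )
        with pytest.raises(ValueError, match="pos_bp"):
            map_to_physical((0.0, 1.0), bare, "1")


class TestAssignInside:
    def _qtl(self):
        return IntervalSet(
            "qtl",
            pd.DataFrame(
                {"chrom": ["c1", "c1"], "start": [100, 180], "end": [200, 300]}
            ),
        )

    def test_midpoint_vs_overlap_rules_differ_on_straddlers(self):
        # item [250, 450): midpoint 350 is outside the merged [100, 300)
        # QTL but the item overlaps it
        items = IntervalSet(
            "genes",
            pd.DataFrame({"chrom": ["c1"], "start": [250], "end": [450]}),
        )
        assert not assign_inside(items, self._qtl(), rule="midpoint")[0]
        assert assign_inside(items, self._qtl(), rule="any_overlap")[0]

    def test_partition_is_exhaustive(self, rng):
        n = 500
        items = IntervalSet(
            "genes",
            pd.DataFrame(
                {
                    "chrom": rng.choice(["c1", "c2"], size=n),
                    "start": (s := rng.integers(0, 10_000, size=n)),
                    "end": s + rng.integers(1, 500, size=n),
                }
            ),
        )
        inside = assign_inside(items, self._qtl())
        outside = ~inside
        assert inside.sum() + outside.sum() == len(items)

    def test_midpoint_matches_naive_loop(self, rng):
        """Vectorized merged-interval search equals a per-item python loop."""
        n = 300
        qtl_rows = []
        for _ in range(8):
            s = int(rng.integers(0, 9_000))
            qtl_rows.append(("c1", s, s + int(rng.integers(100, 2_000))))
        qtl = IntervalSet("qtl", pd.DataFrame(qtl_rows, columns=["chrom", "start", "end"]))
        starts = rng.integers(0, 10_000, size=n)
        items = IntervalSet(
            "it",
            pd.DataFrame(
                {"chrom": "c1", "start": starts, "end": starts + 100}
            ),
        )
        got = assign_inside(items, qtl, rule="midpoint")
        for i, (s, e) in enumerate(zip(items.table["start"], items.table["end"])):
            mid = (s + e) // 2
            expect = any(
                qs <= mid < qe
                for qs, qe in zip(qtl.table["start"], qtl.table["end"])
            )
            assert got[i] == expect, i

    def test_any_overlap_matches_naive_loop(self, rng):
        qtl_rows = []
        for _ in range(6):
            s = int(rng.integers(0, 9_000))
            qtl_rows.append(("c1", s, s + int(rng.integers(100, 2_500))))
        qtl = IntervalSet("qtl", pd.DataFrame(qtl_rows, columns=["chrom", "start", "end"]))
        starts = np.unique(np.random.default_rng(5).integers(0, 10_000, size=200))
        items = IntervalSet(
            "it", pd.DataFrame({"chrom": "c1", "start": starts, "end": starts + 400})
        )
        got = assign_inside(items, qtl, rule="any_overlap")
        for i, (s, e) in enumerate(zip(items.table["start"], items.table["end"])):
            expect = any(
                s < qe and qs < e
                for qs, qe in zip(qtl.table["start"], qtl.table["end"])
            )
            assert got[i] == expect, i

    def test_empty_qtl_set_puts_everything_outside(self):
        items = IntervalSet(
            "it", pd.DataFrame({"chrom": ["c1"], "start": [0], "end": [10]})
        )
        empty = IntervalSet("q", pd.DataFrame(columns=["chrom", "start", "end"]))
        assert not assign_inside(items, empty).any()

    def test_chromosome_isolation(self):
        items = IntervalSet(
            "it", pd.DataFrame({"chrom": ["c2"], "start": [120], "end": [180]})
        )
        assert not assign_inside(items, self._qtl()).any()


class TestPlantedEnrichment:
    GENOME = {"chr1": 2_000_000, "chr2": 1_500_000}

    def test_null_gene_enrichment_uniform_p(self):
        """With equal selected-gene rates inside and outside QTL, the
        chi-square p-values over replicates look uniform."""
        pvals = []
        for seed in range(60):
            ann = simulate_annotations(
                self.GENOME, n_genes=400, n_te=50, n_qtl_intervals=4,
                qtl_length_bp=300_000, seed=seed,
            )
            genes, qtl = ann["genes"], ann["qtl"]
            inside = assign_inside(genes, qtl)
            sel = genes.table["selected"].to_numpy(bool)
            try:
                _, _, p = chisq_2x2(
                    ContingencyTable2x2(
                        int((sel & inside).sum()), int((sel & ~inside).sum()),
                        int((~sel & inside).sum()), int((~sel & ~inside).sum()),
                    )
                )
            except ValueError:
                continue  # degenerate draw
            pvals.append(p)
        assert len(pvals) > 40
        assert stats.kstest(pvals, "uniform").pvalue > 0.01
        assert np.mean(np.array(pvals) < 0.05) < 0.15

    def test_planted_gene_enrichment_detected(self):
        ann = simulate_annotations(
            self.GENOME, n_genes=600, n_te=50, n_qtl_intervals=5,
            qtl_length_bp=400_000, p_selected_inside=0.6,
            p_selected_outside=0.05, seed=13,
        )
        genes, qtl = ann["genes"], ann["qtl"]
        inside = assign_inside(genes, qtl)
        sel = genes.table["selected"].to_numpy(bool)
        _, _, p = chisq_2x2(
            ContingencyTable2x2(
                int((sel & inside).sum()), int((sel & ~inside).sum()),
                int((~sel & inside).sum()), int((~sel & ~inside).sum()),
            )
        )
        assert p < 1e-10


class TestCompareDistributions:
    def _windows(self, n_windows, seed, theta=5.0):
        cfg = CoalescentConfig(n_haplotypes=10, theta=theta,
                               n_windows=n_windows, seed=seed)
        wins = simulate_neutral_windows(cfg)
        out = []
        for i, w in enumerate(wins):
            sm = SiteMatrix(
                "chr1",
                np.arange(1, w.haplotypes.shape[1] + 1) + i * w.window_length_bp,
                w.haplotypes,
                ploidy=1,
            )
            ws = window_stats(sm, window_size=w.window_length_bp,
                              chrom_length=(i + 1) * w.window_length_bp)
            # keep only the window that actually covers these sites
            out.append(ws[-1])
        return out

    def test_null_windows_no_difference(self):
        wins = self._windows(120, seed=21)
        qtl = IntervalSet(
            "qtl",
            pd.DataFrame({"chrom": ["chr1"], "start": [0],
                          "end": [40 * wins[0].end - 40 * wins[0].start]}),
        )
        # first 40 windows inside, rest outside; same neutral process
        rep = compare_distributions(wins, qtl)
        assert rep["groups"]["inside"]["n_windows"] == 40
        assert rep["groups"]["outside"]["n_windows"] == 80
        assert rep["tests"]["pi"]["p"] > 0.001
        assert rep["tests"]["tajima_d"]["p"] > 0.001

    def test_planted_diversity_difference_detected(self):
        lo = self._windows(60, seed=31, theta=1.0)
        hi = self._windows(60, seed=32, theta=12.0)
        size = lo[0].end - lo[0].start
        # relocate the high-diversity windows after the low-diversity ones
        shifted = [
            type(w)(w.chrom, w.start + 60 * size, w.end + 60 * size, w.n_sites,
                    w.pi, w.theta_w, w.tajima_d, w.n_eff, w.flag)
            for w in hi
        ]
        qtl = IntervalSet(
            "qtl",
            pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [60 * size]}),
        )
        rep = compare_distributions(lo + shifted, qtl)
        assert rep["groups"]["inside"]["pi_mean"] < rep["groups"]["outside"]["pi_mean"]
        assert rep["tests"]["pi"]["p"] < 1e-10

    def test_all_windows_outside_reports_skip(self):
        wins = self._windows(10, seed=41)
        qtl = IntervalSet(
            "qtl", pd.DataFrame({"chrom": ["chrX"], "start": [0], "end": [100]})
        )
        rep = compare_distributions(wins, qtl)
        assert rep["groups"]["inside"]["n_windows"] == 0
        assert "skipped" in rep["tests"]

    def test_nan_d_windows_counted_and_excluded(self):
        wins = self._windows(80, seed=51, theta=0.2)  # many monomorphic windows
        size = wins[0].end - wins[0].start
        qtl = IntervalSet(
            "qtl",
            pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [40 * size]}),
        )
        rep = compare_distributions(wins, qtl)
        n_excluded = (
            rep["groups"]["inside"]["n_d_excluded"]
            + rep["groups"]["outside"]["n_d_excluded"]
        )
        n_nan = sum(1 for w in wins if np.isnan(w.tajima_d))
        assert n_excluded == n_nan > 0


class TestTEChangeContrast:
    GENOME = {"chr1": 2_000_000}

    def test_null_te_change_rates(self):
        ann = simulate_annotations(
            self.GENOME, n_genes=10, n_te=1500, n_qtl_intervals=4,
            qtl_length_bp=300_000, seed=71,
        )
        res = te_change_contrast(ann["te_sites"], ann["qtl"], ann["blocks"])
        assert res["df"] == 1
        assert res["p"] > 1e-4  # no planted effect
        assert res["n_sites_in_blocks"] + res["n_sites_dropped"] == len(ann["te_sites"])

    def test_planted_te_change_enrichment_detected(self):
        ann = simulate_annotations(
            self.GENOME, n_genes=10, n_te=2000, n_qtl_intervals=4,
            qtl_length_bp=300_000, p_change_inside=0.8,
            p_change_outside=0.2, seed=81,
        )
        res = te_change_contrast(ann["te_sites"], ann["qtl"], ann["blocks"])
        assert res["p"] < 1e-10
        tab = res["table"]
        rate_in = tab.a / (tab.a + tab.c)
        rate_out = tab.b / (tab.b + tab.d)
        assert rate_in > rate_out

    def test_block_restriction_applied_first(self):
        """TE sites outside all synteny blocks never enter the table."""
        te = IntervalSet(
            "te",
            pd.DataFrame(
                {
                    "chrom": ["chr1"] * 4,
                    "start": [100, 200, 900_100, 900_200],
                    "end": [160, 260, 900_160, 900_260],
                    "changed": [True, False, True, False],
                    "te_class": ["LINE", "LINE", "SINE", "SINE"],
                }
            ),
        )
        blocks = IntervalSet(
            "blk", pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [1_000]})
        )
        qtl = IntervalSet(
            "qtl", pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [180]})
        )
        res = te_change_contrast(te, qtl, blocks)
        assert res["n_sites_in_blocks"] == 2
        assert res["n_sites_dropped"] == 2
        assert (res["table"].a, res["table"].b, res["table"].c, res["table"].d) == (
            1, 0, 0, 1,
        )
        by_class = res["by_class"]
        assert set(by_class["te_class"]) == {"LINE"}

    def test_missing_change_column_rejected(self):
        te = IntervalSet(
            "te", pd.DataFrame({"chrom": ["c"], "start": [0], "end": [10]})
        )
        q = IntervalSet("q", pd.DataFrame({"chrom": ["c"], "start": [0], "end": [5]}))
        with pytest.raises(ValueError, match="changed"):
            te_change_contrast(te, q, q)


class TestTEDistances:
    def test_two_fraction_scalar_case(self):
        """Single shared class at fractions 0.10 and 0.13: distance 0.03."""
        p1 = TEProfile("g1", {"LINE": 100}, 1000)
        p2 = TEProfile("g2", {"LINE": 130}, 1000)
        D = te_distance_matrix([p1, p2])
        assert D.loc["g1", "g2"] == pytest.approx(0.03, abs=1e-12)

    def test_union_of_classes_with_absent_zero(self):
        p1 = TEProfile("g1", {"LINE": 100, "SINE": 50}, 1000)
        p2 = TEProfile("g2", {"LINE": 100, "LTR": 40}, 1000)
        D = te_distance_matrix([p1, p2])
        expected = np.sqrt(0.05**2 + 0.04**2)
        assert D.loc["g1", "g2"] == pytest.approx(expected, abs=1e-12)

    def test_metric_properties_on_simulated_profiles(self):
        df = simulate_te_profiles(n_genomes=6, seed=3)
        profiles = te_profiles_from_table(df)
        D = te_distance_matrix(profiles).to_numpy()
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0.0)
        assert (D[~np.eye(6, dtype=bool)] > 0).all()
        # triangle inequality over all ordered triples
        for i in range(6):
            for j in range(6):
                for k in range(6):
                    assert D[i, j] <= D[i, k] + D[k, j] + 1e-12

    @given(
        st.lists(
            st.tuples(
                st.integers(min_value=0, max_value=10**6),
                st.integers(min_value=0, max_value=10**6),
            ),
            min_size=2,
            max_size=5,
        )
    )
    def test_distance_nonnegative_and_symmetric(self, specs):
        profiles = [
            TEProfile(f"g{i}", {"A": a, "B": b}, 10**7)
            for i, (a, b) in enumerate(specs)
        ]
        D = te_distance_matrix(profiles).to_numpy()
        assert (D >= 0).all()
        assert np.allclose(D, D.T)

    def test_profile_table_roundtrip_and_errors(self):
        df = simulate_te_profiles(n_genomes=3, seed=9)
        profiles = te_profiles_from_table(df)
        assert [p.genome_id for p in profiles] == ["genome1", "genome2", "genome3"]
        bad = df.copy()
        bad.loc[0, "genome_size_bp"] = 1
        with pytest.raises(ValueError, match="inconsistent"):
            te_profiles_from_table(bad)
        with pytest.raises(ValueError, match="at least two"):
            te_distance_matrix(profiles[:1])
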