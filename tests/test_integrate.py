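"""Integrative statistics: attribution, metaprofiles, clustering, tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from striatlas.core import GeneAnnotation, GenomicInterval, SignalTrack
from striatlas.differential import DifferentialRegion, EnhancerCatalogue
from striatlas.integrate import (
    GeneScheme,
    RegionScheme,
    attribute_regions,
    celltype_specificity_enrichment,
    chip_rna_regression,
    chromosome_enrichment,
    cluster_enrichment,
    cluster_gene_profiles,
    concordance_analysis,
    gene_profile_matrix,
    groupwise_zscore_test,
    metaprofile,
    nuclear_fractions,
    top_ranked_genes,
)


def diff_region(chrom, start, end, log2fc, raw_p=1e-3, adj_p=1e-2):
    return DifferentialRegion(
        GenomicInterval(chrom, start, end), log2fc, raw_p, adj_p
    )


def catalogue():
    return EnhancerCatalogue(
        neuronal=[GenomicInterval("chr1", 1000, 3000)],
        glial=[GenomicInterval("chr1", 10_000, 12_000)],
    )


class TestAttribution:
    def test_inside_single_neuronal_entry(self):
        regions = [diff_region("chr1", 1500, 1600, -1.0)]
        out, _ = attribute_regions(regions, catalogue())
        assert out[0].label == "Neuronal"

    def test_dual_overlap_is_non_specific(self):
        cat = EnhancerCatalogue(
            neuronal=[GenomicInterval("chr1", 0, 1000)],
            glial=[GenomicInterval("chr1", 1000, 2000)],
        )
        regions = [diff_region("chr1", 500, 1500, 1.0)]
        out, _ = attribute_regions(regions, cat)
        assert out[0].label == "Non-specific"

    def test_no_overlap_is_non_specific(self):
        regions = [diff_region("chr2", 0, 100, 1.0)]
        out, _ = attribute_regions(regions, catalogue())
        assert out[0].label == "Non-specific"

    def test_labels_partition_the_input(self):
        rng = np.random.default_rng(0)
        regions = [
            diff_region("chr1", int(s), int(s) + 500, float(rng.normal()))
            for s in rng.integers(0, 20_000, size=40)
        ]
        out, table = attribute_regions(regions, catalogue())
        assert len(out) == len(regions)
        assert table["count"].sum() == len(regions)


class TestMetaprofile:
    def _uniform_track(self):
        return SignalTrack(
            100, {"chr1": np.ones(1000)}, normalization_state="rpgc_1x"
        )

    def test_uniform_track_flat_at_one(self):
        mp = metaprofile(
            self._uniform_track(),
            [GenomicInterval("chr1", 40_000, 44_000)],
            RegionScheme(),
        )
        assert np.allclose(mp.mean_profile, 1.0, atol=1e-9)
        assert np.allclose(mp.per_feature_density, 1.0, atol=1e-9)

    def test_gene_scheme_uniform_track_flat(self):
        gene = GeneAnnotation.from_interval(
            "g", GenomicInterval("chr1", 30_000, 42_000, "+")
        )
        mp = metaprofile(self._uniform_track(), [gene], GeneScheme())
        assert np.allclose(mp.mean_profile, 1.0, atol=1e-9)

    def test_triangular_coverage_matches_interpolation_oracle(self):
        # piecewise-linear ramp track: value = bin index
        vals = np.arange(1000, dtype=float)
        track = SignalTrack(100, {"chr1": vals}, normalization_state="rpgc_1x")
        iv = GenomicInterval("chr1", 40_000, 44_000)
        mp = metaprofile(track, [iv], RegionScheme(half_width=2000, bin_bp=100))
        # each 100-bp profile bin aligns with one track bin exactly
        expect = vals[400:440]
        assert np.allclose(mp.mean_profile, expect)

    def test_minus_strand_profile_is_reverse_of_plus(self):
        rng = np.random.default_rng(5)
        track = SignalTrack(
            100, {"chr1": rng.uniform(size=1000)}, normalization_state="rpgc_1x"
        )
        plus = GeneAnnotation.from_interval(
            "gp", GenomicInterval("chr1", 30_000, 40_000, "+")
        )
        minus = GeneAnnotation.from_interval(
            "gm", GenomicInterval("chr1", 30_000, 40_000, "-")
        )
        mp_p = metaprofile(track, [plus], GeneScheme())
        mp_m = metaprofile(track, [minus], GeneScheme())
        assert np.allclose(mp_m.mean_profile, mp_p.mean_profile[::-1])

    def test_out_of_bounds_clipped_with_warning(self):
        with pytest.warns(RuntimeWarning, match="clipped"):
            mp = metaprofile(
                self._uniform_track(),
                [GenomicInterval("chr1", 0, 1000)],
                RegionScheme(),
            )
        assert mp.mean_profile[0] == 0.0  # upstream of the chromosome


class TestClustering:
    def test_two_archetypes_recovered_exactly(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(0)
        a = np.tile([5.0, 0.0, 5.0, 0.0], (30, 1)) + rng.normal(0, 0.1, (30, 4))
        b = np.tile([0.0, 5.0, 0.0, 5.0], (30, 1)) + rng.normal(0, 0.1, (30, 4))
        X = pd.DataFrame(np.vstack([a, b]), index=[f"g{i}" for i in range(60)])
        ca = cluster_gene_profiles(X, k=2, seed=0)
        truth = [0] * 30 + [1] * 30
        assert adjusted_rand_score(truth, ca.labels.to_numpy()) == 1.0

    def test_identical_rows_k1_zero_inertia(self):
        X = pd.DataFrame(np.ones((10, 4)), index=[f"g{i}" for i in range(10)])
        ca = cluster_gene_profiles(X, k=1, seed=0)
        assert ca.inertia == pytest.approx(0.0)

    def test_same_seed_identical_assignment(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(50, 6)), index=[f"g{i}" for i in range(50)])
        a = cluster_gene_profiles(X, k=4, seed=3)
        b = cluster_gene_profiles(X, k=4, seed=3)
        assert (a.labels == b.labels).all()

    def test_k_exceeding_genes_rejected(self):
        X = pd.DataFrame(np.ones((3, 2)), index=list("abc"))
        with pytest.raises(ValueError):
            cluster_gene_profiles(X, k=5)


class TestClusterEnrichment:
    def _assignment(self, sizes, seed=0):
        gene_ids = [f"g{i}" for i in range(sum(sizes))]
        labels = np.repeat(np.arange(len(sizes)), sizes)
        from striatlas.integrate import ClusterAssignment

        return ClusterAssignment(
            labels=pd.Series(labels, index=gene_ids),
            centroids=np.zeros((len(sizes), 1)),
            inertia=0.0,
            k=len(sizes),
        )

    def _de(self, gene_ids, rng):
        return pd.DataFrame(
            {
                "gene_id": gene_ids,
                "log2fc": -np.abs(rng.normal(size=len(gene_ids))),
                "raw_p": rng.uniform(size=len(gene_ids)),
                "adj_p": rng.uniform(size=len(gene_ids)),
            }
        )

    def test_uniform_top_genes_not_enriched(self):
        rng = np.random.default_rng(0)
        ca = self._assignment([50, 50, 50, 50])
        hits = 0
        for trial in range(20):
            de = self._de(list(ca.labels.index), np.random.default_rng(trial))
            table = cluster_enrichment(de, ca, top_n=40)
            hits += (table["adj_p"] >= 0.5).all()
        assert hits >= 15  # adjusted p >= 0.5 in most null draws

    def test_concentrated_top_genes_extreme_p(self):
        ca = self._assignment([20, 180])
        rng = np.random.default_rng(1)
        de = self._de(list(ca.labels.index), rng)
        de.loc[de["gene_id"].isin(ca.members(0)), "raw_p"] = 0.0  # cluster 0 tops
        table = cluster_enrichment(de, ca, top_n=20)
        assert table.loc[table["cluster"] == 0, "raw_p"].iloc[0] < 1e-15

    def test_single_cluster_p_one(self):
        ca = self._assignment([100])
        de = self._de(list(ca.labels.index), np.random.default_rng(2))
        table = cluster_enrichment(de, ca, top_n=30)
        assert table["raw_p"].iloc[0] == 1.0

    def test_top_n_too_large_rejected(self):
        ca = self._assignment([10, 10])
        de = self._de(list(ca.labels.index), np.random.default_rng(3))
        with pytest.raises(ValueError):
            cluster_enrichment(de, ca, top_n=100)

    def test_rank_tie_break_deterministic(self):
        de = pd.DataFrame(
            {
                "gene_id": ["b", "a", "c"],
                "log2fc": [-1.0, -1.0, -1.0],
                "raw_p": [0.5, 0.5, 0.1],
                "adj_p": [0.5, 0.5, 0.1],
            }
        )
        assert top_ranked_genes(de, 2, "raw_p", "down") == ["c", "a"]


class TestSpecificityEnrichment:
    def _table(self, n_neuronal=50, n_glial=50):
        rows = []
        for i in range(n_neuronal):
            rows.append({"gene_id": f"n{i}", "log2fc": 2.0, "adj_p": 1e-4})
        for i in range(n_glial):
            rows.append({"gene_id": f"g{i}", "log2fc": -2.0, "adj_p": 1e-4})
        rows.append({"gene_id": "x", "log2fc": 0.1, "adj_p": 0.9})
        return pd.DataFrame(rows)

    def test_balanced_top_set_p_one(self):
        res = celltype_specificity_enrichment(
            ["n0", "n1", "g0", "g1"], self._table()
        )
        assert res.p_value == 1.0
        assert res.null_proportion == 0.5

    def test_thirty_to_zero_enumeration(self):
        top = [f"n{i}" for i in range(30)]
        res = celltype_specificity_enrichment(top, self._table())
        assert res.p_value == pytest.approx(2.0 * 2.0**-30, rel=1e-9)

    def test_no_specific_genes_errors(self):
        table = pd.DataFrame(
            [{"gene_id": "a", "log2fc": 0.0, "adj_p": 0.9}]
        )
        with pytest.raises(ValueError):
            celltype_specificity_enrichment(["a"], table)


class TestChipRnaRegression:
    def test_identity_gives_perfect_fit(self):
        t = pd.DataFrame(
            {
                "gene_id": list("abcde"),
                "chip_log2fc": [1.0, -2.0, 0.5, 3.0, -1.0],
                "rna_log2fc": [1.0, -2.0, 0.5, 3.0, -1.0],
                "rna_adj_p": [0.5] * 5,
            }
        )
        res = chip_rna_regression(t)
        row = res[res["stratum"] == "all"].iloc[0]
        assert row["pearson_r"] == pytest.approx(1.0)
        assert row["slope"] == pytest.approx(1.0)

    def test_five_point_closed_form(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0])
        t = pd.DataFrame(
            {
                "gene_id": list("abcde"),
                "chip_log2fc": x,
                "rna_log2fc": y,
                "rna_adj_p": [0.5] * 5,
            }
        )
        res = chip_rna_regression(t)
        row = res[res["stratum"] == "all"].iloc[0]
        r_expect = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert row["pearson_r"] == pytest.approx(r_expect)

    def test_constant_predictor_errors(self):
        t = pd.DataFrame(
            {
                "gene_id": list("abc"),
                "chip_log2fc": [1.0, 1.0, 1.0],
                "rna_log2fc": [1.0, 2.0, 3.0],
                "rna_adj_p": [0.5] * 3,
            }
        )
        with pytest.raises(ValueError):
            chip_rna_regression(t)


class TestConcordance:
    def _lists(self, fcs):
        g, a = [], []
        for i, (fg, fa, pg, pa) in enumerate(fcs):
            iv = GenomicInterval("chr1", i * 1000, i * 1000 + 500)
            g.append(DifferentialRegion(iv, fg, pg, pg))
            a.append(DifferentialRegion(iv, fa, pa, pa))
        return g, a

    def test_hand_table_half_concordant(self):
        g, a = self._lists(
            [
                (1.0, 1.0, 0.01, 0.01),
                (1.0, -1.0, 0.01, 0.01),
                (-1.0, 1.0, 0.01, 0.01),
                (-1.0, -1.0, 0.01, 0.01),
            ]
        )
        res = concordance_analysis(g, a, catalogue())
        assert res.concordance == pytest.approx(0.5)

    def test_filter_respects_both_contrasts(self):
        g, a = self._lists(
            [
                (1.0, 1.0, 0.01, 0.01),
                (1.0, 1.0, 0.5, 0.01),  # fails genotype filter
                (1.0, 1.0, 0.01, 0.5),  # fails age filter
            ]
        )
        res = concordance_analysis(g, a, catalogue())
        assert len(res.table) == 1

    def test_empty_retained_set_errors_with_diagnostics(self):
        g, a = self._lists([(1.0, 1.0, 0.5, 0.5)])
        with pytest.raises(ValueError, match="genotype: 0"):
            concordance_analysis(g, a, catalogue())

    def test_different_universes_rejected(self):
        g, _ = self._lists([(1.0, 1.0, 0.01, 0.01)])
        _, a = self._lists([(1.0, 1.0, 0.01, 0.01), (1.0, 1.0, 0.01, 0.01)])
        with pytest.raises(ValueError, match="universe"):
            concordance_analysis(g, a, catalogue())

    def test_zmatrix_ordering(self):
        g, a = self._lists([(1.0, 1.0, 0.01, 0.01), (-1.0, -1.0, 0.01, 0.01)])
        signal = pd.DataFrame(
            np.array([[1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0]]),
            index=["chr1:0-500", "chr1:1000-1500"],
            columns=list("wxyz"),
        )
        res = concordance_analysis(g, a, catalogue(), signal=signal)
        assert res.zmatrix.shape == (2, 4)
        assert sorted(res.row_order.tolist()) == [0, 1]


class TestChromosomeEnrichment:
    def _universe(self, sizes):
        genes = []
        for chrom, n in sizes.items():
            for i in range(n):
                genes.append(
                    GeneAnnotation.from_interval(
                        f"{chrom}_g{i}",
                        GenomicInterval(chrom, i * 1000, i * 1000 + 500),
                    )
                )
        return genes

    def _de(self, gene_ids, sig, universe):
        chrom_of = {g.gene_id: g.interval.chrom for g in universe}
        return pd.DataFrame(
            {
                "gene_id": gene_ids,
                "adj_p": [1e-4 if s else 0.9 for s in sig],
                "chromosome": [chrom_of[g] for g in gene_ids],
            }
        )

    def test_uniform_sampling_not_enriched(self):
        uni = self._universe({"chr1": 100, "chr2": 100})
        rng = np.random.default_rng(0)
        ids = [g.gene_id for g in uni]
        passed = 0
        for trial in range(10):
            chosen = set(
                np.random.default_rng(trial).choice(ids, size=30, replace=False)
            )
            de = self._de(ids, [g in chosen for g in ids], uni)
            table = chromosome_enrichment(de, uni)
            passed += (table["adj_p"] > 0.05).all()
        assert passed >= 9

    def test_concentrated_degs_extreme_p(self):
        uni = self._universe({"chr1": 20, "chr2": 180})
        ids = [g.gene_id for g in uni]
        sig = [g.startswith("chr1") for g in ids]  # all 20 DEGs on chr1 (10%)
        de = self._de(ids, sig, uni)
        table = chromosome_enrichment(de, uni)
        assert table.loc[table["chromosome"] == "chr1", "raw_p"].iloc[0] < 1e-10
        assert table.loc[table["chromosome"] == "chr1", "pct_of_degs"].iloc[0] == 100.0

    def test_single_chromosome_p_one(self):
        uni = self._universe({"chr1": 50})
        ids = [g.gene_id for g in uni]
        de = self._de(ids, [True] * 10 + [False] * 40, uni)
        table = chromosome_enrichment(de, uni)
        assert table["raw_p"].iloc[0] == 1.0

    def test_unknown_chromosome_rejected(self):
        uni = self._universe({"chr1": 10})
        de = pd.DataFrame(
            {"gene_id": ["x"], "adj_p": [1e-4], "chromosome": ["chr9"]}
        )
        with pytest.raises(ValueError):
            chromosome_enrichment(de, uni)


class TestGroupwiseZscore:
    def _expr(self, rng, n_genes=20, shift=None):
        cols = [f"a{i}" for i in range(3)] + [f"b{i}" for i in range(3)]
        x = rng.normal(10, 2, size=(n_genes, 6))
        if shift:
            x[:, 3:] += shift
        return pd.DataFrame(x, index=[f"g{i}" for i in range(n_genes)], columns=cols)

    def _groups(self):
        return pd.Series(
            ["A"] * 3 + ["B"] * 3,
            index=[f"a{i}" for i in range(3)] + [f"b{i}" for i in range(3)],
        )

    def test_identical_distributions_null(self):
        rng = np.random.default_rng(0)
        expr = self._expr(rng)
        res = groupwise_zscore_test(expr, list(expr.index), self._groups())
        assert res.p_value > 0.05

    def test_three_group_hand_formula(self):
        # KW H on 3 groups of 3 with no ties, via the textbook rank formula
        groups = [np.array([1.2, 3.4, 5.6]), np.array([2.1, 4.3, 6.5]), np.array([0.7, 7.8, 8.9])]
        all_vals = np.concatenate(groups)
        ranks = stats.rankdata(all_vals)
        n = len(all_vals)
        h_expect = 12.0 / (n * (n + 1)) * sum(
            len(g) * ranks[i * 3 : (i + 1) * 3].mean() ** 2 for i, g in enumerate(groups)
        ) - 3 * (n + 1)
        h_got, _ = stats.kruskal(*groups)
        assert h_got == pytest.approx(h_expect, rel=1e-12)

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(1)
        expr = self._expr(rng, n_genes=50, shift=2.0)
        res = groupwise_zscore_test(expr, list(expr.index), self._groups())
        assert res.p_value < 0.01
        assert (res.pairwise["adj_p"] < 0.01).all()

    def test_small_group_rejected(self):
        rng = np.random.default_rng(2)
        expr = self._expr(rng)
        groups = pd.Series(
            ["A"] * 5 + ["B"],
            index=expr.columns,
        )
        with pytest.raises(ValueError):
            groupwise_zscore_test(expr, list(expr.index), groups)


class TestNuclearFractions:
    def test_printed_formula(self):
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")
            assert nuclear_fractions(30, 70) == (30.0, 70.0)

    def test_single_sided(self):
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")
            assert nuclear_fractions(1, 0) == (100.0, 0.0)

    def test_low_event_warning_below_threshold(self):
        with pytest.warns(RuntimeWarning, match="30000"):
            pos, neg = nuclear_fractions(29_998, 1)
        assert pos + neg == pytest.approx(100.0)

    def test_no_warning_at_threshold(self):
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("error")
            nuclear_fractions(20_000, 10_000)

    def test_zero_total_errors(self):
        with pytest.raises(ValueError):
            nuclear_fractions(0, 0)
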