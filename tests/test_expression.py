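"""Gene assignment, fold changes, rank-sum tests, metagene and distance decay."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dsbmap.expression import (
    GeneRecord,
    assign_sites_to_genes,
    classify_site_location,
    compare_fc_distributions,
    distance_decay,
    estimate_decay_length,
    gene_fold_changes,
    gene_proximity_enrichment,
    metagene_profile,
    site_gene_distance,
    tss_class_enrichment,
)


def _gene(gene_id="g1", chrom="chr1", start=10_000, end=20_000, strand="+", **kw):
    tss, tes = (start, end - 1) if strand == "+" else (end - 1, start)
    return GeneRecord(gene_id=gene_id, chrom=chrom, tss=tss, tes=tes,
                      strand=strand, **kw)


class TestAssignment:
    GENE = _gene()

    def test_upstream_within_flank(self):
        df = assign_sites_to_genes({"s": ("chr1", 9_500)}, [self.GENE])
        assert df.iloc[0]["distance"] == 500

    def test_outside_flank_not_assigned(self):
        df = assign_sites_to_genes({"s": ("chr1", 30_000)}, [self.GENE])
        assert df.empty

    def test_inside_gene_distance_zero(self):
        df = assign_sites_to_genes({"s": ("chr1", 15_000)}, [self.GENE])
        assert df.iloc[0]["distance"] == 0

    def test_site_may_map_to_multiple_genes(self):
        genes = [self.GENE, _gene("g2", start=19_000, end=30_000)]
        df = assign_sites_to_genes({"s": ("chr1", 19_500)}, genes)
        assert set(df["gene_id"]) == {"g1", "g2"}


class TestLocationClass:
    def test_upstream_of_plus_strand_tss_is_promoter(self):
        assert classify_site_location(8_500, _gene()) == "promoter_tss"

    def test_upstream_of_minus_strand_tss_is_promoter(self):
        assert classify_site_location(21_000, _gene(strand="-")) == "promoter_tss"

    def test_inside_coding_exon_is_gene_body(self):
        gene = _gene(
            exons=((10_000, 12_000), (15_000, 20_000)),
            thick=(11_000, 19_000),
        )
        assert classify_site_location(16_000, gene) == "gene_body"

    def test_five_prime_utr_exon_is_promoter_class(self):
        gene = _gene(
            exons=((10_000, 12_000), (15_000, 20_000)),
            thick=(11_000, 19_000),
        )
        assert classify_site_location(10_500, gene) == "promoter_tss"

    def test_far_site_is_intergenic(self):
        assert classify_site_location(60_000, _gene()) == "intergenic"

    def test_intron_is_gene_body(self):
        gene = _gene(exons=((10_000, 12_000), (15_000, 20_000)),
                     thick=(11_000, 19_000))
        assert classify_site_location(13_000, gene) == "gene_body"


class TestFoldChanges:
    def test_log2_with_pseudocount(self):
        counts = pd.DataFrame(
            {"ind": [50, 1000], "unind": [100, 1000]}, index=["g1", "stable"]
        )
        fc = gene_fold_changes(
            counts, {"ind": "induced", "unind": "uninduced"}, norm="cpm"
        )
        # equal library sizes are forced by the stable gene dominating totals
        expected = math.log2((50 * 1e6 / 1050 + 1) / (100 * 1e6 / 1100 + 1))
        assert fc["g1"] == pytest.approx(expected, abs=0.02)

    def test_median_of_ratios_corrects_depth(self):
        # library twice as deep, no real change: logFC ~ 0
        counts = pd.DataFrame(
            {"ind": [200, 400, 600], "unind": [100, 200, 300]},
            index=["a", "b", "c"],
        )
        fc = gene_fold_changes(counts, {"ind": "induced", "unind": "uninduced"})
        assert np.allclose(fc, 0.0, atol=1e-9)

    def test_cpm_mode_example(self):
        counts = pd.DataFrame(
            {"ind": [100, 2_000_000 - 100], "unind": [100, 1_000_000 - 100]},
            index=["g1", "rest"],
        )
        fc = gene_fold_changes(
            counts, {"ind": "induced", "unind": "uninduced"}, norm="cpm"
        )
        assert fc["g1"] == pytest.approx(math.log2(51 / 101), abs=1e-6)

    def test_zero_counts_give_zero_logfc(self):
        counts = pd.DataFrame(
            {"ind": [0, 500], "unind": [0, 500]}, index=["g1", "stable"]
        )
        fc = gene_fold_changes(counts, {"ind": "induced", "unind": "uninduced"})
        assert fc["g1"] == 0.0

    def test_missing_condition_errors(self):
        counts = pd.DataFrame({"a": [1]}, index=["g"])
        with pytest.raises(ValueError):
            gene_fold_changes(counts, {"a": "induced"})

    def test_control_gene_normalization(self):
        rng = np.random.default_rng(0)
        base = rng.integers(100, 1000, 50)
        counts = pd.DataFrame(
            {"ind": base.copy(), "unind": base.copy()},
            index=[f"g{i}" for i in range(50)],
        )
        counts.iloc[:25, 0] //= 4  # half the genes strongly down when induced
        fc = gene_fold_changes(
            counts,
            {"ind": "induced", "unind": "uninduced"},
            control_genes=[f"g{i}" for i in range(25, 50)],
        )
        assert fc.iloc[25:].abs().max() < 0.05


class TestRankSum:
    def test_exact_p_for_separated_groups(self):
        res = compare_fc_distributions([-1, -1, -1, -1], [0, 0, 0, 0])
        assert res.method == "exact"
        assert res.p_value == pytest.approx(1 / 70)

    def test_identical_multisets_not_significant(self):
        res = compare_fc_distributions([1, 2, 3], [1, 2, 3])
        assert res.p_value >= 0.5

    def test_wrong_direction_near_one(self):
        res = compare_fc_distributions([2, 3, 4], [0, 1, 1.5], alternative="less")
        assert res.p_value > 0.9

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            compare_fc_distributions([], [1.0])

    def test_ecdfs_returned(self):
        res = compare_fc_distributions([1, 2], [3, 4])
        x, y = res.ecdf_cut
        assert x.tolist() == [1, 2] and y.tolist() == [0.5, 1.0]

    def test_exact_matches_full_permutation_oracle(self):
        """Tie-aware DP equals enumeration of every label assignment (n <= 8)."""
        rng = np.random.default_rng(29)
        for _ in range(60):
            n1 = int(rng.integers(1, 5))
            n2 = int(rng.integers(1, 5))
            pooled = rng.integers(0, 4, n1 + n2).astype(float)  # heavy ties
            x, y = pooled[:n1], pooled[n1:]
            res = compare_fc_distributions(x, y, method="exact")
            ranks = stats.rankdata(pooled)
            obs = ranks[:n1].sum()
            total = 0
            le = 0
            for idx in itertools.combinations(range(n1 + n2), n1):
                total += 1
                le += ranks[list(idx)].sum() <= obs + 1e-9
            assert res.p_value == pytest.approx(le / total)

    def test_asymptotic_branch_used_for_large_groups(self):
        rng = np.random.default_rng(31)
        res = compare_fc_distributions(
            rng.normal(size=150), rng.normal(size=150)
        )
        assert res.method == "asymptotic"
        assert 0 < res.p_value < 1


class TestMetagene:
    def _cov(self, length=50_000, value=3.0):
        return {"chr1": np.full(length, value)}

    def test_constant_coverage_gives_flat_profile(self):
        prof = metagene_profile(self._cov(), [_gene()], n_bins=20)
        assert np.allclose(prof.mean_rpm, prof.mean_rpm[0])

    def test_rpm_invariant_under_duplication(self):
        genes = [_gene()]
        cov = {"chr1": np.arange(50_000, dtype=float)}
        p1 = metagene_profile(cov, genes, n_bins=20)
        p2 = metagene_profile({"chr1": cov["chr1"] * 2}, genes, n_bins=20)
        np.testing.assert_allclose(p1.mean_rpm, p2.mean_rpm)

    def test_minus_strand_runs_tss_to_tes(self):
        cov = {"chr1": np.arange(50_000, dtype=float)}
        plus = metagene_profile(cov, [_gene()], n_bins=20)
        minus = metagene_profile(cov, [_gene(strand="-")], n_bins=20)
        np.testing.assert_allclose(minus.mean_rpm, plus.mean_rpm[::-1])

    def test_splice_concatenates_exons(self):
        cov = {"chr1": np.zeros(50_000)}
        cov["chr1"][10_000:12_000] = 6.0
        cov["chr1"][15_000:20_000] = 6.0  # introns stay 0
        gene = _gene(exons=((10_000, 12_000), (15_000, 20_000)))
        prof = metagene_profile(cov, [gene], n_bins=20, splice=True)
        assert np.allclose(prof.mean_rpm, prof.mean_rpm[0])
        assert prof.mean_rpm[0] > 0

    def test_short_gene_skipped_with_warning(self):
        genes = [_gene(), _gene("tiny", start=100, end=140)]
        with pytest.warns(UserWarning, match="skipped 1"):
            prof = metagene_profile(self._cov(), genes, n_bins=50)
        assert prof.n_genes == 1


class TestDistanceDecay:
    def test_two_point_disjoint_binning(self):
        res = distance_decay([50, 900_000], [-1.0, -0.1], scheme="disjoint")
        assert res.mean_logfc[0] == pytest.approx(-1.0)
        assert res.mean_logfc[3] == pytest.approx(-0.1)  # (100, 1000] kb bin
        assert res.fit_slope > 0

    def test_all_zero_fold_changes(self):
        res = distance_decay([10, 500, 5_000, 50_000], [0, 0, 0, 0],
                             scheme="cumulative")
        assert np.allclose(res.mean_logfc, 0)
        assert res.fit_slope == pytest.approx(0.0)

    def test_cumulative_bins_accumulate(self):
        res = distance_decay([50, 900_000], [-1.0, -0.1], scheme="cumulative")
        assert res.gene_counts.tolist() == [1, 1, 1, 2]

    def test_constant_width_bins(self):
        res = distance_decay(
            [50_000, 250_000, 450_000], [-1.0, -0.5, -0.1],
            edges_kb=(200.0,), scheme="constant",
        )
        assert res.gene_counts.tolist() == [1, 1, 1]

    def test_empty_bin_excluded_from_fit(self):
        res = distance_decay([50], [-1.0], scheme="disjoint")
        assert res.gene_counts[1:].sum() == 0
        assert np.isnan(res.mean_logfc[1])

    def test_recovers_noiseless_decay_length(self):
        d = np.logspace(2, 6, 200)
        f = -1.2 * np.exp(-d / 10_000.0)
        lam, b = estimate_decay_length(d, f)
        assert lam == pytest.approx(10_000, rel=0.15)
        assert b == pytest.approx(1.2, rel=0.1)


class TestTssEnrichment:
    def test_hand_checked_hypergeometric_example(self):
        """4 down-TSSs of 10; cut sites over 3 of them: p = C(4,3)/C(10,3)."""
        down = [[10.0, 2.0]] * 4
        up = [[2.0, 10.0]] * 6
        expr = pd.DataFrame(
            down + up, columns=["unind", "ind"],
            index=[f"t{i}" for i in range(10)],
        )
        pos = pd.DataFrame(
            {"chrom": ["chr1"] * 10, "pos": [i * 100_000 for i in range(10)]},
            index=expr.index,
        )
        cut = [("chr1", 0), ("chr1", 100_000), ("chr1", 200_000)]
        res = tss_class_enrichment(
            expr, {"unind": "uninduced", "ind": "induced"}, pos, cut, k=2,
        )
        assert res.table.tolist() == [[3, 1], [0, 6]]
        assert res.p_value == pytest.approx(4 / 120)

    def test_no_overlap_gives_p_one(self):
        expr = pd.DataFrame(
            [[10.0, 2.0]] * 4 + [[2.0, 10.0]] * 6,
            columns=["unind", "ind"], index=[f"t{i}" for i in range(10)],
        )
        pos = pd.DataFrame(
            {"chrom": ["chr1"] * 10, "pos": [i * 100_000 for i in range(10)]},
            index=expr.index,
        )
        res = tss_class_enrichment(
            expr, {"unind": "uninduced", "ind": "induced"}, pos,
            [("chr9", 5)], k=2,
        )
        assert res.p_value == 1.0

    def test_k_larger_than_distinct_profiles_errors(self):
        expr = pd.DataFrame(
            [[1.0, 2.0]] * 5, columns=["unind", "ind"],
            index=[f"t{i}" for i in range(5)],
        )
        pos = pd.DataFrame(
            {"chrom": ["chr1"] * 5, "pos": range(5)}, index=expr.index
        )
        with pytest.raises(ValueError, match="distinct"):
            tss_class_enrichment(
                expr, {"unind": "uninduced", "ind": "induced"}, pos, [], k=3
            )

    def test_fisher_matches_hypergeometric_enumeration(self):
        """One-sided Fisher p equals the hypergeometric tail for all tables
        with margins <= 12."""
        for n_down in range(0, 13):
            for n_not in range(0, 13 - n_down):
                total = n_down + n_not
                if total == 0:
                    continue
                for n_cut in range(0, total + 1):
                    for a in range(max(0, n_cut - n_not), min(n_down, n_cut) + 1):
                        table = [
                            [a, n_down - a],
                            [n_cut - a, n_not - (n_cut - a)],
                        ]
                        _, p = stats.fisher_exact(table, alternative="greater")
                        oracle = sum(
                            math.comb(n_down, x) * math.comb(n_not, n_cut - x)
                            for x in range(a, min(n_down, n_cut) + 1)
                        ) / math.comb(total, n_cut)
                        assert p == pytest.approx(oracle, rel=1e-9)


class TestGeneProximity:
    LENGTHS = {"chr1": 10_000}
    GENE = [_gene(start=2_000, end=5_000)]  # +/-1 kb flank covers 1000..6000

    def test_all_sites_near_genes(self):
        sites = [("chr1", 1_500 + 400 * i) for i in range(10)]
        res = gene_proximity_enrichment(sites, self.GENE, self.LENGTHS, flank=1_000)
        assert res["p0"] == pytest.approx(0.5)
        assert res["k_near_genes"] == 10
        assert res["p_value"] == pytest.approx(2 ** -10)

    def test_half_near_genes_matches_tail_summation(self):
        sites = [("chr1", 1_500 + 400 * i) for i in range(5)] + [
            ("chr1", 6_500 + 400 * i) for i in range(5)
        ]
        res = gene_proximity_enrichment(sites, self.GENE, self.LENGTHS, flank=1_000)
        oracle = sum(
            math.comb(10, k) * 0.5**10 for k in range(res["k_near_genes"], 11)
        )
        assert res["p_value"] == pytest.approx(oracle)

    def test_no_sites_near_genes(self):
        sites = [("chr1", 8_000 + 100 * i) for i in range(10)]
        res = gene_proximity_enrichment(sites, self.GENE, self.LENGTHS, flank=1_000)
        assert res["k_near_genes"] == 0
        assert res["p_value"] == pytest.approx(1.0)


class TestDistances:
    def test_distance_convention(self):
        g = _gene()
        assert site_gene_distance(9_500, g) == 500
        assert site_gene_distance(15_000, g) == 0
        assert site_gene_distance(20_500, g) == 501  # from last base at 19,999
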