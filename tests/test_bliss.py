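"""BLISS read filtering, per-site quantification, normalization and ranking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dsbmap.bliss import (
    ReadRecord,
    call_cut_sites,
    filter_reads,
    normalize_local_global,
    quantify_library,
    quantify_site,
    quantile_normalize_pair,
    rank_cut_sites,
)
from dsbmap.digest import GenomicWindow, RestrictionSite


def _read(chrom="chr1", start=0, end=50, strand="+", **kw):
    return ReadRecord(chrom=chrom, start=start, end=end, strand=strand, **kw)


class TestFilterReads:
    def test_exact_barcode_kept(self):
        res = filter_reads([_read(barcode="ATCGT")], "ATCGT", max_mismatch=0)
        assert len(res.reads) == 1 and res.n_barcode_dropped == 0

    def test_one_mismatch_dropped_at_zero_tolerance(self):
        with pytest.warns(UserWarning):
            res = filter_reads([_read(barcode="ATCGA")], "ATCGT", max_mismatch=0)
        assert res.reads == [] and res.n_barcode_dropped == 1

    def test_one_mismatch_kept_with_tolerance(self):
        res = filter_reads([_read(barcode="ATCGA")], "ATCGT", max_mismatch=1)
        assert len(res.reads) == 1

    def test_wrong_length_barcode_dropped_not_error(self):
        with pytest.warns(UserWarning):
            res = filter_reads([_read(barcode="ATC")], "ATCGT")
        assert res.reads == [] and res.n_barcode_dropped == 1

    def test_dedup_collapses_identical_key(self):
        reads = [_read(umi="AACC"), _read(umi="AACC"), _read(umi="GGTT")]
        res = filter_reads(reads, dedup=True)
        assert len(res.reads) == 2 and res.n_duplicates_removed == 1

    def test_all_dropped_warns(self):
        with pytest.warns(UserWarning, match="all reads dropped"):
            filter_reads([_read(barcode="AAAAA")], "CCCCC")


class TestQuantifySite:
    WIN = GenomicWindow("chr1", 0, 200, False)

    def test_single_read(self):
        cf, rc = quantify_site(self.WIN, [_read(start=10, end=60)])
        assert cf == pytest.approx(0.25)
        assert rc == 1

    def test_union_of_overlapping_reads(self):
        reads = [_read(start=0, end=100), _read(start=50, end=150)]
        cf, rc = quantify_site(self.WIN, reads)
        assert cf == pytest.approx(0.75)
        assert rc == 2

    def test_empty(self):
        assert quantify_site(self.WIN, []) == (0.0, 0.0)

    def test_zero_length_window_errors(self):
        with pytest.raises(ValueError, match="zero-length"):
            quantify_site(GenomicWindow("chr1", 5, 5, False), [])

    def test_minus_strand_five_prime_is_right_end(self):
        # 5' end at 249 is outside [0, 200): no originating read
        cf, rc = quantify_site(self.WIN, [_read(start=150, end=250, strand="-")])
        assert rc == 0 and cf == pytest.approx(0.25)

    def test_agrees_with_per_base_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            win = GenomicWindow("chr1", 100, 100 + int(rng.integers(50, 300)), False)
            reads = []
            for _ in range(int(rng.integers(0, 30))):
                s = int(rng.integers(0, 500))
                e = s + int(rng.integers(1, 80))
                strand = "+-"[int(rng.integers(0, 2))]
                reads.append(_read(start=s, end=e, strand=strand))
            cf, rc = quantify_site(win, reads)
            covered = np.zeros(win.end - win.start, dtype=bool)
            n5 = 0
            for r in reads:
                lo, hi = max(r.start, win.start), min(r.end, win.end)
                if lo < hi:
                    covered[lo - win.start : hi - win.start] = True
                if win.start <= r.five_prime < win.end:
                    n5 += 1
            assert cf == pytest.approx(covered.mean())
            assert rc == n5

    def test_pileup_origin_counts_window_bases_of_originating_reads(self):
        cf, rc = quantify_site(self.WIN, [_read(start=180, end=230)], mode="pileup-origin")
        assert rc == 20  # read starts inside, contributes its in-window bases
        cf2, rc2 = quantify_site(
            self.WIN, [_read(start=180, end=230, strand="-")], mode="pileup-origin"
        )
        assert rc2 == 0  # 5' end (right) outside the window


class TestNormalization:
    def _df(self, pairs):
        return pd.DataFrame(
            pairs, columns=["rc", "cf"], index=[f"s{i}" for i in range(len(pairs))]
        )[["cf", "rc"]]

    def test_local_normalization_formula(self):
        out = normalize_local_global(self._df([(10, 0.5), (10, 1.0), (40, 1.0)]))
        assert out["ln"].tolist() == [20.0, 10.0, 40.0]

    def test_global_normalization_by_median(self):
        out = normalize_local_global(self._df([(20, 1.0), (10, 1.0), (40, 1.0)]))
        assert out["gn"].tolist() == [1.0, 0.5, 2.0]

    def test_empty_window_convention(self):
        out = normalize_local_global(self._df([(0, 0.0), (10, 1.0), (40, 1.0)]))
        assert out["ln"].iloc[0] == 0.0

    def test_degenerate_library_errors(self):
        with pytest.raises(ValueError, match="degenerate library"):
            normalize_local_global(self._df([(0, 0.0), (0, 0.0)]))

    def test_degenerate_passthrough_keeps_ln(self):
        out = normalize_local_global(
            self._df([(0, 0.0), (0, 0.0)]), degenerate="passthrough"
        )
        assert (out["gn"] == out["ln"]).all()

    def test_median_gn_is_one(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(2, 40))
            rc = rng.integers(1, 100, n).astype(float)
            cf = rng.uniform(0.1, 1.0, n)
            out = normalize_local_global(self._df(list(zip(rc, cf))))
            assert np.median(out["gn"]) == pytest.approx(1.0)


class TestQuantileNormalize:
    def test_rank_matching(self):
        qn, unchanged = quantile_normalize_pair([5, 1, 3], [2, 8, 4])
        assert qn.tolist() == [8.0, 2.0, 4.0]
        assert unchanged.tolist() == [2.0, 8.0, 4.0]

    def test_identical_vectors_unchanged(self):
        qn, _ = quantile_normalize_pair([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert qn.tolist() == [1.0, 2.0, 3.0]

    def test_ties_get_mean_of_tied_ranks(self):
        qn, _ = quantile_normalize_pair([3, 3], [1, 5])
        assert qn.tolist() == [3.0, 3.0]

    def test_length_mismatch_and_empty_error(self):
        with pytest.raises(ValueError):
            quantile_normalize_pair([1, 2], [1])
        with pytest.raises(ValueError):
            quantile_normalize_pair([], [])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.floats(0, 1e6, allow_nan=False), min_size=1, max_size=30, unique=True
        ).flatmap(
            lambda u: st.tuples(
                st.permutations(u),
                st.lists(
                    st.floats(0, 1e6, allow_nan=False),
                    min_size=len(u),
                    max_size=len(u),
                ),
            )
        )
    )
    def test_sorted_equality_and_idempotence(self, pair):
        induced, uninduced = pair
        qn1, _ = quantile_normalize_pair(induced, uninduced)
        # tie-free induced: the two sorted multisets coincide exactly
        assert sorted(qn1.tolist()) == sorted(float(u) for u in uninduced)
        qn2, _ = quantile_normalize_pair(qn1, uninduced)
        assert qn2.tolist() == qn1.tolist()


class TestRanking:
    def _quants(self, rows):
        df = pd.DataFrame(
            rows,
            columns=["chrom", "motif_start", "qn_induced", "qn_uninduced", "rc_induced"],
        )
        df.index = [f"{c}:{m}" for c, m in zip(df["chrom"], df["motif_start"])]
        return df

    def test_ratio_with_pseudocount(self):
        out = rank_cut_sites(self._quants([("chr1", 0, 99.0, 0.0, 50.0)]))
        assert out["ratio"].iloc[0] == pytest.approx(100.0)
        assert out["log2ratio"].iloc[0] == pytest.approx(6.644, abs=1e-3)

    def test_equal_counts_not_called(self):
        out = rank_cut_sites(self._quants([("chr1", 0, 5.0, 5.0, 50.0)]))
        assert out["log2ratio"].iloc[0] == 0.0
        assert not out["called"].iloc[0]

    def test_tie_broken_by_coordinates(self):
        out = rank_cut_sites(
            self._quants(
                [("chr2", 5, 8.0, 1.0, 50.0), ("chr1", 9, 8.0, 1.0, 50.0)]
            )
        )
        assert list(out.index) == ["chr1:9", "chr2:5"]
        assert out["rank"].tolist() == [1, 2]

    def test_negative_qn_errors(self):
        with pytest.raises(ValueError, match="negative"):
            rank_cut_sites(self._quants([("chr1", 0, -1.0, 0.0, 5.0)]))

    def test_ranks_are_a_permutation(self, bliss_table):
        assert sorted(bliss_table["rank"]) == list(
            range(1, len(bliss_table) + 1)
        )


class TestZeroBackgroundCalling:
    """With no background reads, detection is exact: every cut site with
    enough break-end reads is called and no uncut site is."""

    def test_planted_sites_called_exactly(self):
        rng = np.random.default_rng(13)
        # half the sites uncut, as in the genomic reality the scenario mimics
        efficiencies = [0.0, 0.3, 0.0, 0.5, 0.0, 0.7, 0.0, 1.0]
        sites, windows, reads = [], [], []
        for i, e in enumerate(efficiencies):
            center = 10_000 + 5_000 * i
            sites.append(
                RestrictionSite("chr1", center - 4, center + 4, center, f"chr1:{center - 4}")
            )
            windows.append(GenomicWindow("chr1", center - 100, center + 100, False))
            n = int(round(50 * e))
            for _ in range(n):
                p5 = center + int(rng.integers(-90, 90))
                reads.append(_read(start=p5, end=p5 + 50))
        table = call_cut_sites(sites, windows, reads, [])
        called = {
            sid for sid, row in table.iterrows() if row["called"]
        }
        expected = {
            s.site_id for s, e in zip(sites, efficiencies) if e > 0
        }
        assert called == expected
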