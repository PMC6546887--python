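"""Length summaries, splice-site usage, chi-square, junction matrices."""

import numpy as np
import pytest

from asland.as_classifier import enumerate_events
from asland.feature_stats import (
    boundary_dinucleotides, chi_square_homogeneity, junction_matrix,
    length_summary, as_fragment_sizes, site_category, splice_site_usage,
    usage_counts, usage_table,
)
from asland.genomic_model import GenomicInterval, cluster_loci
from asland._util import revcomp


def iv(start, end, chrom="c", strand="+"):
    return GenomicInterval(chrom, start, end, strand)


class TestLengthSummary:
    def test_single_length(self):
        s = length_summary([100])
        assert (s.n, s.mean, s.sd) == (1, 100.0, 0.0)
        assert s.min == s.max == 100

    def test_bins_are_right_inclusive(self):
        s = length_summary([1, 100, 101], bin_width=100)
        assert s.histogram == {100: 2, 200: 1}

    def test_empty_sentinel(self):
        s = length_summary([])
        assert s.n == 0 and s.mean is None and s.histogram == {}

    def test_moments_match_two_pass_naive_computation(self):
        rng = np.random.default_rng(1)
        lengths = np.maximum(1, rng.lognormal(5, 1.5, 10_000).astype(int))
        s = length_summary(lengths.tolist())
        mean = sum(lengths) / len(lengths)
        sd = (sum((x - mean) ** 2 for x in lengths) / (len(lengths) - 1)) ** 0.5
        assert abs(s.mean - mean) < 1e-9
        assert abs(s.sd - sd) < 1e-9
        assert s.n == sum(s.histogram.values())


class TestFragmentSizes:
    def test_planted_fragments_match_truth(self, bundle_large, large_events):
        _, events, by_pair = large_events
        truth = bundle_large.truth.events
        planted = {}
        recovered = []
        for row in truth.itertuples():
            key = tuple(sorted((row.ref_id, row.alt_id)))
            evs = by_pair.get(key, [])
            if len(evs) == 1:
                planted.setdefault(row.event_type, []).append(
                    int(row.fragment_size))
                recovered.append(evs[0])
        summaries = as_fragment_sizes(recovered)
        for t in ("IntronR", "AltA", "AltD", "ExonS"):
            got = summaries[t]
            expected = length_summary(planted[t])
            assert got.n == expected.n
            assert got.mean == pytest.approx(expected.mean)
            assert got.min == expected.min and got.max == expected.max


class TestBoundaryDinucleotides:
    GENOME = {"c": "AAAAA" + "GT" + "TTTTTT" + "AG" + "CCCCC"}
    # intron spans [5, 15): GT......AG on the plus strand

    def test_plus_strand_reads_canonical_pair(self):
        (pair,) = boundary_dinucleotides([iv(5, 15)], self.GENOME)
        assert pair == ("GT", "AG")

    def test_minus_strand_reverse_complements(self):
        genome = {"c": revcomp(self.GENOME["c"])}
        # the same intron mirrored: genomic CT..AC, transcript-oriented GT..AG
        (pair,) = boundary_dinucleotides([iv(5, 15, strand="-")], genome)
        assert pair == ("GT", "AG")
        assert genome["c"][5:7] == "CT" and genome["c"][13:15] == "AC"

    def test_short_introns_skipped(self):
        assert boundary_dinucleotides([iv(5, 8)], self.GENOME) == []

    def test_category_assignment(self):
        assert site_category("GT", "AG") == "GT..AG"
        assert site_category("CT", "AC") == "CT..AC"
        assert site_category("NN", "AG") == "Others"
        assert site_category("TT", "TT") == "Others"


class TestUsageTable:
    # genome-wide totals of a published usage table; exercises the
    # percentage rule on real-scale counts
    TOTALS = {"GT..AG": 255669, "GC..AG": 7571, "GC..AT": 3060,
              "AT..AC": 2751, "CT..AC": 2067, "GT..AT": 2036, "Others": 9142}
    NON_AS = {"GT..AG": 41053, "GC..AG": 1511, "GC..AT": 712,
              "AT..AC": 844, "CT..AC": 232, "GT..AT": 554, "Others": 1208}

    def test_total_column_percentages(self):
        as_counts = {k: self.TOTALS[k] - self.NON_AS[k] for k in self.TOTALS}
        df = usage_table(self.NON_AS, as_counts)
        assert df.loc["GT..AG", "Total"] == 255669
        assert df.loc["Total", "Total"] == 282296
        assert df.loc["GT..AG", "Total (%)"] == 90.6
        assert df.loc["GT..AG", "Non-AS (%)"] == 89.0
        assert df.loc["GT..AG", "AS (%)"] == 90.9

    def test_percentages_sum_to_100_within_rounding(self):
        as_counts = {k: self.TOTALS[k] - self.NON_AS[k] for k in self.TOTALS}
        df = usage_table(self.NON_AS, as_counts)
        for col in ("Total (%)", "Non-AS (%)", "AS (%)"):
            assert abs(df.loc[list(self.TOTALS), col].sum() - 100.0) <= 0.3


class TestChiSquare:
    def test_identical_composition_gives_zero_statistic(self):
        counts = {"GT..AG": 90, "GC..AG": 10}
        res = chi_square_homogeneity(counts, counts)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_two_by_two_matches_hand_calculation(self):
        # O = [[10,20],[30,40]]; E_ij = row_i * col_j / 100
        a = {"GT..AG": 10, "GC..AG": 30}
        b = {"GT..AG": 20, "GC..AG": 40}
        hand = (
            (10 - 30 * 40 / 100) ** 2 / (30 * 40 / 100)
            + (20 - 30 * 60 / 100) ** 2 / (30 * 60 / 100)
            + (30 - 70 * 40 / 100) ** 2 / (70 * 40 / 100)
            + (40 - 70 * 60 / 100) ** 2 / (70 * 60 / 100)
        )
        res = chi_square_homogeneity(a, b, pool_threshold=0)
        assert res.statistic == pytest.approx(hand)
        assert hand == pytest.approx(0.79365, abs=1e-5)
        assert res.df == 1

    def test_low_expected_categories_pool_into_others(self):
        a = {"GT..AG": 500, "GC..AG": 30, "GT..AT": 2, "Others": 10}
        b = {"GT..AG": 480, "GC..AG": 40, "GT..AT": 1, "Others": 12}
        res = chi_square_homogeneity(a, b)
        assert "GT..AT" in res.pooled_categories

    def test_zero_group_raises(self):
        with pytest.raises(ValueError):
            chi_square_homogeneity({"GT..AG": 10}, {"GT..AG": 0})


class TestSpliceSiteUsage:
    def test_end_to_end_on_synthetic_genome(self, bundle_large, large_events):
        loci, events, _ = large_events
        with_events = {e.locus_id for e in events}
        as_introns, non_as = [], []
        for locus in loci:
            target = as_introns if locus.id in with_events else non_as
            for t in locus.transcripts:
                target.extend(t.introns)
        if not non_as:  # all-AS simulation: split arbitrarily for the test
            non_as = as_introns[: len(as_introns) // 2]
            as_introns = as_introns[len(as_introns) // 2:]
        table, chi = splice_site_usage(as_introns, non_as, bundle_large.genome)
        assert table.loc["Total", "Total"] == int(
            table.loc[list(self_categories()), "Total"].sum())
        assert 0.0 <= chi.p_value <= 1.0


def self_categories():
    from asland.feature_stats import SITE_CATEGORIES
    return list(SITE_CATEGORIES)


class TestJunctionMatrix:
    def test_single_intron_columns_are_unit_vectors(self):
        genome = {"c": "ACGTACGTAC" + "GTAAAAAAAG" + "GTACGTACGT" * 2}
        profile = junction_matrix([iv(10, 20)], genome)
        for col in range(1, 21):
            assert profile.five_prime[col].max() == pytest.approx(1.0)
            assert profile.five_prime[col].sum() == pytest.approx(1.0)

    def test_canonical_introns_pin_intron_start_columns(self, bundle_large):
        ref = bundle_large.truth.introns
        canon = ref[(ref.origin == "ref") & (ref.site_type == "GT..AG")]
        introns = [
            iv(int(r.start), int(r.end), chrom=r.chrom, strand=r.strand)
            for r in canon.head(300).itertuples()
        ]
        profile = junction_matrix(introns, bundle_large.genome)
        # positions 11-12 of the 5' matrix are the first intronic bases
        assert profile.five_prime.loc["G", 11] == pytest.approx(1.0)
        assert profile.five_prime.loc["T", 12] == pytest.approx(1.0)
        # positions 9-10 of the 3' matrix are the last intronic bases
        assert profile.three_prime.loc["A", 9] == pytest.approx(1.0)
        assert profile.three_prime.loc["G", 10] == pytest.approx(1.0)

    def test_matches_naive_per_position_counting(self, bundle_large):
        ref = bundle_large.truth.introns
        rows = ref[ref.origin == "ref"].head(1000)
        introns = [
            iv(int(r.start), int(r.end), chrom=r.chrom, strand=r.strand)
            for r in rows.itertuples()
        ]
        profile = junction_matrix(introns, bundle_large.genome)
        # naive recount of the 5' window
        counts = {b: np.zeros(20) for b in "ACGT"}
        genome = bundle_large.genome
        n = 0
        for intron in introns:
            seq = genome[intron.chrom]
            if intron.strand == "-":
                window = revcomp(seq[intron.end - 10: intron.end + 10])
            else:
                window = seq[intron.start - 10: intron.start + 10]
            if len(window) < 20:
                continue
            n += 1
            for j, base in enumerate(window.upper()):
                if base in counts:
                    counts[base][j] += 1
        assert profile.n_introns == n
        for b in "ACGT":
            np.testing.assert_allclose(
                profile.five_prime.loc[b].to_numpy(), counts[b] / n,
                atol=1e-12)
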