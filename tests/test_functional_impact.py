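"""ORF prediction, domain-impact categories, gene-model assignment, TE overlap."""

import numpy as np
import pytest

from asland.as_classifier import enumerate_events
from asland.functional_impact import (
    ASRateReport, TEOverlapReport,
    as_rate, assign_transcripts_to_gene_models, categorize_event_domains,
    find_orfs, impact_percentages, te_overlap_fraction,
)
from asland.genomic_model import (
    GeneModel, GenomicInterval, Transcript, cluster_loci,
)
from oracles import brute_longest_orf, random_dna


def iv(start, end, chrom="c", strand="+"):
    return GenomicInterval(chrom, start, end, strand)


def tx(tid, exons, chrom="c", strand="+"):
    return Transcript(tid, tuple(iv(s, e, chrom, strand) for s, e in exons))


class TestFindORFs:
    def test_minimal_complete_orf(self):
        orfs = find_orfs("ATGAAATAG", min_aa=0)
        (orf,) = [o for o in orfs if o.longest]
        assert (orf.start, orf.end, orf.aa_length) == (0, 9, 2)
        assert orf.full_length and orf.has_start and orf.has_stop

    def test_no_atg_no_stop_yields_three_frame_orfs(self):
        seq = "CCC" * 20  # no ATG, no stop in any frame
        orfs = find_orfs(seq, min_aa=0)
        assert len(orfs) == 3
        assert {o.frame for o in orfs} == {0, 1, 2}
        assert not any(o.full_length or o.has_start or o.has_stop for o in orfs)

    def test_empty_sequence(self):
        assert find_orfs("", min_aa=0) == []

    def test_min_aa_drops_short_records(self):
        assert find_orfs("ATGAAATAG", min_aa=30) == []

    def test_structural_invariants(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            for orf in find_orfs(random_dna(rng, 600), min_aa=0):
                assert (orf.end - orf.start) % 3 == 0
                assert orf.aa_length == (orf.end - orf.start) // 3 - (
                    1 if orf.has_stop else 0)
                assert orf.full_length == (orf.has_start and orf.has_stop)

    def test_longest_orf_matches_bruteforce(self):
        rng = np.random.default_rng(31337)
        compared = 0
        for _ in range(200):
            seq = random_dna(rng, int(rng.integers(30, 1200)))
            orfs = find_orfs(seq, min_aa=10)
            expected = brute_longest_orf(seq, min_aa=10)
            if expected is None:
                assert orfs == []
                continue
            (best,) = [o for o in orfs if o.longest]
            assert (best.aa_length, best.start, best.end,
                    best.has_start, best.has_stop) == expected
            compared += 1
        assert compared > 150


class TestDomainImpact:
    def test_category_rules(self, bundle_small):
        from asland.functional_impact import pair_category
        assert pair_category({}, "a", "b") == "both_none"
        d = {"a": {"PF00069"}, "b": {"PF00069"}}
        assert pair_category(d, "a", "b") == "same"
        d = {"a": {"PF00069"}}
        assert pair_category(d, "a", "b") == "one_lost"
        d = {"a": {"PF00069"}, "b": {"PF00071"}}
        assert pair_category(d, "a", "b") == "different"
        # empty set counts as unannotated
        d = {"a": set(), "b": {"PF00069"}}
        assert pair_category(d, "a", "b") == "one_lost"

    def test_published_scale_counts_round_to_expected_percentages(self):
        rep = impact_percentages({
            "both_none": 114729, "same": 164594,
            "one_lost": 64107, "different": 26481,
        })
        assert rep.total == 369911
        assert rep.percentages == {
            "both_none": 31.0, "same": 44.5, "one_lost": 17.3,
            "different": 7.2,
        }
        assert rep.loss_or_change == 90588
        assert rep.loss_or_change_pct == 24.5

    def test_categories_partition_events(self, bundle_large, large_events):
        _, events, _ = large_events
        rep = categorize_event_domains(events, bundle_large.domains)
        assert sum(rep.counts.values()) == len(events)

    def test_planted_categories_recovered(self, bundle_small, large_events):
        bundle = bundle_small
        loci = cluster_loci(bundle.transcripts)
        events = [e for l in loci for e in enumerate_events(l)]
        by_pair = {}
        for e in events:
            by_pair.setdefault((e.tx_a, e.tx_b), []).append(e)
        from asland.functional_impact import pair_category
        for row in bundle.truth.pairs.itertuples():
            key = tuple(sorted((row.ref_id, row.alt_id)))
            if key in by_pair:
                assert pair_category(bundle.domains, row.ref_id,
                                     row.alt_id) == row.category


class TestAssignment:
    def _setup(self, seq, mutate_every=None):
        """A model at [0, L) and a transcript copy at an offset locus."""
        L = len(seq)
        copy = list(seq)
        if mutate_every:
            for i in range(0, L, mutate_every):
                copy[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[copy[i]]
        genome = {"c": seq + "N" * 50 + "".join(copy)}
        model = GeneModel("m1", tx("m1.t", [(0, L)]), seq)
        transcript = tx("q", [(L + 50, 2 * L + 50)])
        return genome, model, transcript

    def test_exact_copy_matches(self):
        rng = np.random.default_rng(4)
        seq = random_dna(rng, 600)
        genome, model, t = self._setup(seq)
        assignment, expressed = assign_transcripts_to_gene_models(
            [t], [model], genome)
        assert assignment == {"q": "m1"}
        assert expressed == {"m1"}

    def test_79_nt_shared_block_is_insufficient(self):
        # mismatched bases flanking the block stop it extending past 79 nt
        rng = np.random.default_rng(8)
        block = random_dna(rng, 79)
        model_seq = random_dna(rng, 199) + "A" + block + "A" + random_dna(rng, 199)
        q_seq = random_dna(rng, 99) + "C" + block + "C" + random_dna(rng, 99)
        genome = {"c": model_seq + q_seq}
        model = GeneModel("m1", tx("m1.t", [(0, len(model_seq))]), model_seq)
        t = tx("q", [(len(model_seq), len(model_seq) + len(q_seq))])
        assignment, _ = assign_transcripts_to_gene_models([t], [model], genome)
        assert assignment == {}

    def test_80_nt_shared_block_is_sufficient(self):
        rng = np.random.default_rng(8)
        block = random_dna(rng, 80)
        model_seq = random_dna(rng, 200) + block + random_dna(rng, 200)
        q_seq = random_dna(rng, 100) + block + random_dna(rng, 100)
        genome = {"c": model_seq + q_seq}
        model = GeneModel("m1", tx("m1.t", [(0, len(model_seq))]), model_seq)
        t = tx("q", [(len(model_seq), len(model_seq) + len(q_seq))])
        assignment, _ = assign_transcripts_to_gene_models([t], [model], genome)
        assert assignment == {"q": "m1"}

    def test_snv_density_controls_matchability(self):
        rng = np.random.default_rng(12)
        seq = random_dna(rng, 600)
        genome, model, t = self._setup(seq, mutate_every=60)
        assignment, _ = assign_transcripts_to_gene_models([t], [model], genome)
        assert assignment == {}  # max shared run 59 < 80
        genome, model, t = self._setup(seq, mutate_every=200)
        assignment, _ = assign_transcripts_to_gene_models([t], [model], genome)
        assert assignment == {"q": "m1"}  # shared runs of 199 >= 80

    def test_bundle_transcripts_map_to_their_gene(self, bundle_small):
        b = bundle_small
        assignment, expressed = assign_transcripts_to_gene_models(
            b.transcripts, b.models, b.genome)
        for t in b.transcripts:
            gene = t.id.split(".")[0]
            assert assignment.get(t.id) == gene
        assert expressed == {t.id.split(".")[0] for t in b.transcripts}


class TestASRate:
    def test_published_scale_counts_round_to_expected_rates(self):
        rep = ASRateReport.from_counts(23233, 34522, 35768)
        assert rep.rate_expressed == 67.3
        assert rep.rate_all == 65.0

    def test_zero_as_genes(self):
        rep = ASRateReport.from_counts(0, 10, 20)
        assert rep.rate_expressed == 0.0 and rep.rate_all == 0.0

    def test_monotonicity_and_bundle_consistency(self, bundle_small):
        b = bundle_small
        loci = cluster_loci(b.transcripts)
        events = [e for l in loci for e in enumerate_events(l)]
        assignment, _ = assign_transcripts_to_gene_models(
            b.transcripts, b.models, b.genome)
        rep = as_rate(events, assignment, b.models)
        assert rep.as_gene_models <= rep.expressed_gene_models <= rep.all_gene_models
        assert rep.rate_expressed >= rep.rate_all
        truth_as_genes = set(b.truth.events.gene_id)
        assert rep.as_gene_models == len(truth_as_genes)


class TestTEOverlap:
    def test_published_scale_counts_round_to_expected_fractions(self):
        rep = TEOverlapReport.from_counts(812, 68241, 3105, 138127)
        assert rep.fraction_retained == 1.2
        assert rep.fraction_all == 2.2

    def test_overlap_requires_at_least_one_bp(self):
        introns = [iv(100, 300)]
        rep = te_overlap_fraction([], introns, [iv(300, 400)], min_intron_bp=50)
        assert rep.all_with_te == 0  # half-open: touching is not overlap
        rep = te_overlap_fraction([], introns, [iv(299, 400)], min_intron_bp=50)
        assert rep.all_with_te == 1

    def test_planted_density_recovered(self):
        from asland.synthetic_data import SimConfig, generate
        b = generate(SimConfig(n_genes=400, te_density=0.10), seed=99)
        introns = [
            iv(int(r.start), int(r.end), chrom=r.chrom, strand=r.strand)
            for r in b.truth.introns[b.truth.introns.origin == "ref"].itertuples()
        ]
        rep = te_overlap_fraction(introns, introns, b.te_intervals)
        n = rep.all_total
        p = 0.10
        ci = 2.576 * (p * (1 - p) / n) ** 0.5
        assert abs(rep.all_with_te / n - p) <= ci
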