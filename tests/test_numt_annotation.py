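import numpy as np
import pytest

from numtkit.io_formats import GenomicInterval, SequenceRecord, SeqRole
from numtkit.hsp_discovery import CircularInterval
from numtkit.numt_annotation import (
    MergeParams,
    NumtHSP,
    classify_genomic_context,
    coverage_profile,
    merge_hsps,
    refine_locus,
    summarize_assembly,
    unify_numt_lists,
    _mergeable,
)
from numtkit import synth_fixtures as sf
from oracles import brute_force_merge

L = 16727


def hsp(seq, ns, ne, ms, me, strand="+", identity=95.0):
    if ms < me:
        circ = CircularInterval(L, ((ms, me),))
    else:  # origin-spanning shorthand
        circ = CircularInterval(L, ((ms, L), (0, me)))
    return NumtHSP(GenomicInterval(seq, ns, ne, strand), circ, strand, identity, len(circ))


class TestMergeRule:
    def test_within_gap_merges(self):
        a = hsp("chr1", 1000, 1200, 100, 300)
        b = hsp("chr1", 2500, 2700, 350, 550)
        loci = merge_hsps([a, b])
        assert len(loci) == 1
        assert loci[0].total_aligned_bp == 400
        assert loci[0].nuclear_span.start == 1000 and loci[0].nuclear_span.end == 2700

    def test_nuclear_gap_over_2000_splits(self):
        a = hsp("chr1", 1000, 1200, 100, 300)
        b = hsp("chr1", 3701, 3900, 350, 550)  # gap 2501
        assert len(merge_hsps([a, b])) == 2

    def test_mito_gap_over_2000_splits(self):
        a = hsp("chr1", 1000, 1200, 100, 300)
        b = hsp("chr1", 2500, 2700, 2400, 2600)  # mito gap 2100
        assert len(merge_hsps([a, b])) == 2

    def test_opposite_strand_splits(self):
        a = hsp("chr1", 1000, 1200, 100, 300)
        b = hsp("chr1", 2500, 2700, 350, 550, strand="-")
        assert len(merge_hsps([a, b])) == 2

    def test_minus_strand_requires_descending_mito_order(self):
        # on the minus strand, nuclear order must reverse mito order
        a = hsp("chr1", 1000, 1200, 350, 550, strand="-")
        b = hsp("chr1", 2500, 2700, 100, 300, strand="-")
        assert len(merge_hsps([a, b])) == 1
        # ascending mito order on the minus strand is inconsistent
        a2 = hsp("chr1", 1000, 1200, 100, 300, strand="-")
        b2 = hsp("chr1", 2500, 2700, 350, 550, strand="-")
        assert len(merge_hsps([a2, b2])) == 2

    def test_merge_across_circle_origin(self):
        a = hsp("chr1", 1000, 1500, 16200, 16727)
        b = hsp("chr1", 1600, 1900, 10, 310)
        assert len(merge_hsps([a, b])) == 1

    def test_merge_conserves_hsps(self):
        rng = np.random.default_rng(0)
        hsps = [
            hsp("chr1", s, s + 200, m, m + 200)
            for s, m in zip(
                rng.integers(0, 100_000, 40), rng.integers(0, L - 200, 40)
            )
        ]
        loci = merge_hsps(hsps)
        assert sum(len(l.members) for l in loci) == len(hsps)
        assert len(loci) <= len(hsps)

    def test_matches_brute_force_closure_on_random_instances(self):
        """The union-find merge equals a fixed-point sweep over the same
        pairwise predicate on many random HSP sets."""
        rng = np.random.default_rng(123)
        params = MergeParams()
        for _ in range(200):
            n = int(rng.integers(2, 15))
            hsps = []
            for _ in range(n):
                s = int(rng.integers(0, 20_000))
                ln = int(rng.integers(50, 2000))
                m = int(rng.integers(0, L - 1))
                mlen = int(rng.integers(50, 3000))
                strand = "+" if rng.random() < 0.7 else "-"
                ms, me = m, min(m + mlen, L)
                hsps.append(hsp("chr1", s, s + ln, ms, me, strand=strand))
            loci = merge_hsps(hsps, params)
            got = sorted(
                sorted((h.nuclear.start, h.nuclear.end) for h in l.members)
                for l in loci
            )
            oracle_groups = brute_force_merge(
                hsps, 2000, 2000, lambda a, b: _mergeable(a, b, params)
            )
            expected = sorted(
                sorted((hsps[i].nuclear.start, hsps[i].nuclear.end) for i in g)
                for g in oracle_groups
            )
            assert got == expected


class TestRefineLocus:
    def test_origin_spanning_refines_to_single_comma_pair_hsp(self, small_mito):
        Ls = len(small_mito.sequence)
        segment = small_mito.sequence[-300:] + small_mito.sequence[:300]
        locus_seq = SequenceRecord(
            "locus1", sf.random_dna(400, 1) + segment + sf.random_dna(400, 2)
        )
        members = refine_locus(locus_seq, small_mito)
        assert len(members) == 1
        assert members[0].mito.spans_origin
        assert members[0].mito.segments == ((Ls - 300, Ls), (0, 300))
        assert members[0].aligned_mito_bp == 600

    def test_diverged_locus_identity_in_expected_band(self, small_mito):
        segment = small_mito.sequence[1000:2000]
        diverged = sf.mutate(segment, 0.05, 0.0, seed=21)
        locus_seq = SequenceRecord("locus2", diverged)
        members = refine_locus(locus_seq, small_mito)
        assert len(members) == 1
        # 99% binomial CI around 95% identity for n=1000 is ~ +/-1.8 points
        assert 93.0 <= members[0].percent_identity <= 97.0

    def test_random_locus_unconfirmed(self, small_mito):
        locus_seq = SequenceRecord("locus3", sf.random_dna(2000, 33))
        assert refine_locus(locus_seq, small_mito) == []


class TestSummaries:
    def test_single_hsp_counts(self):
        locus = merge_hsps([hsp("chr1", 0, 100, 0, 100)])[0]
        summary = summarize_assembly([locus], {"chr1": SeqRole.chromosome})
        row = summary.row(SeqRole.chromosome)
        assert row == {
            "hsp_count": 1,
            "total_size_bp": 100,
            "max_length_bp": 100,
            "median_length_bp": 100.0,
            "merged_locus_count": 1,
        }
        assert summary.row(SeqRole.unplaced)["hsp_count"] == 0

    def test_even_count_median_is_midpoint(self):
        loci = merge_hsps(
            [hsp("chr1", 0, 100, 0, 100), hsp("chr2", 0, 200, 5000, 5200)]
        )
        summary = summarize_assembly(
            loci, {"chr1": SeqRole.chromosome, "chr2": SeqRole.chromosome}
        )
        assert summary.row(SeqRole.chromosome)["median_length_bp"] == 150.0

    def test_stratification_separates_unplaced(self):
        loci = merge_hsps(
            [hsp("chr1", 0, 100, 0, 100), hsp("chrUn_1", 0, 300, 2000, 2300)]
        )
        summary = summarize_assembly(
            loci, {"chr1": SeqRole.chromosome, "chrUn_1": SeqRole.unplaced}
        )
        assert summary.row(SeqRole.chromosome)["hsp_count"] == 1
        assert summary.row(SeqRole.unplaced)["total_size_bp"] == 300


class TestCoverageProfile:
    def test_simple_interval(self):
        cov = coverage_profile([hsp("chr1", 0, 100, 0, 100)], L)
        assert cov[:100].sum() == 100 and cov.sum() == 100

    def test_origin_spanning_counts_both_ends(self):
        h = hsp("chr1", 0, 100, L - 50, 50)
        cov = coverage_profile([h], L)
        assert cov.sum() == 100
        assert cov[L - 1] == 1 and cov[0] == 1 and cov[5000] == 0

    def test_total_equals_aligned_bp(self, basic_loci):
        members = [m for l in basic_loci for m in l.members]
        cov = coverage_profile(members, 16_727)
        assert cov.sum() == sum(m.aligned_mito_bp for m in members)


class TestUnify:
    def _iv(self, start, end, chrom="chr1"):
        return GenomicInterval(chrom, start, end)

    def test_within_tolerance_collapses(self):
        regions = unify_numt_lists(
            {"a": [self._iv(100, 500)], "b": [self._iv(105, 505)]}
        )
        assert len(regions) == 1
        assert regions[0].start == 100 and regions[0].end == 505
        assert regions[0].sources == {"a", "b"}

    def test_start_difference_over_tolerance_splits(self):
        regions = unify_numt_lists(
            {"a": [self._iv(100, 500)], "b": [self._iv(111, 500)]}
        )
        assert len(regions) == 2

    def test_order_independence(self):
        rng = np.random.default_rng(77)
        lists = {}
        for src in "abcd":
            lists[src] = [
                self._iv(int(s), int(s) + int(l))
                for s, l in zip(
                    rng.integers(0, 5000, 12), rng.integers(100, 400, 12)
                )
            ]
        fwd = unify_numt_lists(lists)
        rev = unify_numt_lists(dict(reversed(list(lists.items()))))
        key = lambda rs: [(r.seq_name, r.start, r.end, tuple(sorted(r.sources))) for r in rs]
        assert key(fwd) == key(rev)

    def test_mismatched_references_rejected(self):
        class Locus:
            def __init__(self, ref):
                self.seq_name, self.start, self.end = "chr1", 0, 100
                self.reference = ref

        with pytest.raises(ValueError, match="mismatched"):
            unify_numt_lists({"a": [Locus("asm1")], "b": [Locus("asm2")]})


class TestGenomicContext:
    GENES = [GenomicInterval("chr1", 1000, 9000)]
    EXONS = [GenomicInterval("chr1", 1000, 1500), GenomicInterval("chr1", 8000, 9000)]
    CPG = [GenomicInterval("chr1", 4900, 5100)]

    def test_labels(self):
        regions = [
            GenomicInterval("chr1", 2000, 2400),  # intron, no exon
            GenomicInterval("chr1", 1200, 1300),  # inside an exon
            GenomicInterval("chr1", 20_000, 20_500),  # outside genes
        ]
        labels = classify_genomic_context(regions, self.GENES, self.EXONS, self.CPG)
        assert [l.label for l in labels] == ["intronic", "exonic", "intergenic"]
        assert [l.cpg_flag for l in labels] == [False, False, False]

    def test_cpg_flag_any_overlap(self):
        region = GenomicInterval("chr1", 5099, 5400)  # 1 bp CpG overlap
        label = classify_genomic_context([region], self.GENES, self.EXONS, self.CPG)[0]
        assert label.cpg_flag is True
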