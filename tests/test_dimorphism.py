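import numpy as np
import pytest

from numtkit.io_formats import GenomicInterval, SequenceRecord
from numtkit.hsp_discovery import CircularInterval
from numtkit.numt_annotation import NumtHSP
from numtkit.dimorphism_assemblies import (
    DimorphismParams,
    IndelVariant,
    call_absence,
    call_novel_insertions,
    compare_identity_groups,
    overlap_fraction,
)
from numtkit import synth_fixtures as sf
from oracles import brute_force_overlap_calls, welch_closed_form

L = 16727


def iv(start, end, chrom="chr1"):
    return GenomicInterval(chrom, start, end)


def hsp(start, end, chrom="chr1"):
    length = end - start
    return NumtHSP(
        iv(start, end, chrom), CircularInterval(L, ((0, length),)), "+", 95.0, length
    )


def deletion(start, end, chrom="chr1", label="asm2"):
    return IndelVariant("deletion", iv(start, end, chrom), end - start, label)


@pytest.mark.parametrize(
    "a,b,expected",
    [
        ((0, 100), (5, 100), 0.95),
        ((0, 100), (200, 300), 0.0),
        ((0, 100), (0, 100), 1.0),
        ((50, 150), (0, 100), 0.5),
    ],
)
def test_overlap_fraction(a, b, expected):
    assert overlap_fraction(iv(*a), iv(*b)) == pytest.approx(expected)


def test_overlap_fraction_zero_across_chromosomes():
    assert overlap_fraction(iv(0, 100, "chr1"), iv(0, 100, "chr2")) == 0.0


class TestCallAbsence:
    def test_hsp_inside_similar_sized_deletion_is_clean(self):
        # a 195 bp HSP entirely within a 210 bp deletion: cleanly dimorphic
        calls = call_absence([hsp(1000, 1195)], [deletion(995, 1205)])
        assert calls[0].status == "absent_clean"
        assert calls[0].supporting[0][0] == "asm2"

    def test_hsp_inside_much_larger_deletion_is_large_sv(self):
        calls = call_absence([hsp(2000, 2300)], [deletion(0, 5000)])
        assert calls[0].status == "absent_large_sv"

    def test_below_overlap_threshold_stays_fixed(self):
        # deletion covers 260/300 = 0.867 < 0.90
        calls = call_absence([hsp(0, 300)], [deletion(40, 300)])
        assert calls[0].status == "fixed"

    def test_exactly_90_percent_is_absent(self):
        calls = call_absence([hsp(0, 1000)], [deletion(100, 1000)])
        assert calls[0].status == "absent_clean"

    def test_large_sv_margin_boundary(self):
        # variant exactly HSP + 1000 long is NOT a large SV (strict >)
        calls = call_absence([hsp(5000, 5300)], [deletion(4350, 5650)])
        assert calls[0].status == "absent_clean"
        calls = call_absence([hsp(5000, 5300)], [deletion(4350, 5651)])
        assert calls[0].status == "absent_large_sv"

    def test_partition_is_exhaustive(self):
        hsps = [hsp(i * 10_000, i * 10_000 + 500) for i in range(20)]
        dels = [deletion(50_000, 50_600), deletion(100_000, 110_000)]
        calls = call_absence(hsps, dels)
        assert len(calls) == len(hsps)
        by_status = {}
        for c in calls:
            by_status[c.status] = by_status.get(c.status, 0) + 1
        assert sum(by_status.values()) == 20

    def test_matches_brute_force_scan_on_random_fixtures(self):
        rng = np.random.default_rng(99)
        params = DimorphismParams()
        for _ in range(50):
            n, m = int(rng.integers(1, 30)), int(rng.integers(1, 30))
            hsps = []
            triples = []
            for _ in range(n):
                s = int(rng.integers(0, 50_000))
                l = int(rng.integers(50, 2000))
                hsps.append(hsp(s, s + l))
                triples.append(("chr1", s, s + l))
            dels = []
            dtriples = []
            for _ in range(m):
                s = int(rng.integers(0, 50_000))
                l = int(rng.integers(50, 6000))
                dels.append(deletion(s, s + l))
                dtriples.append(("chr1", s, s + l))
            got = [c.status for c in call_absence(hsps, dels, params)]
            expected = brute_force_overlap_calls(triples, dtriples, 0.90, 1000)
            assert got == expected


class TestNovelInsertions:
    def insertion(self, seq, label="asm3"):
        return IndelVariant("insertion", iv(10, 11), len(seq), label, sequence=seq)

    def test_pure_mito_insertion_is_clean(self, small_mito):
        var = self.insertion(small_mito.sequence[500:900])
        calls = call_novel_insertions([var], small_mito)
        assert len(calls) == 1
        assert calls[0].status == "inserted_clean"

    def test_mito_segment_embedded_in_long_insertion_is_large_sv(self, small_mito):
        seq = (
            sf.random_dna(2200, 1) + small_mito.sequence[1000:1600] + sf.random_dna(2200, 2)
        )
        calls = call_novel_insertions([self.insertion(seq)], small_mito)
        assert calls[0].status == "inserted_large_sv"

    def test_random_insertion_yields_no_call(self, small_mito):
        calls = call_novel_insertions(
            [self.insertion(sf.random_dna(400, 12345))], small_mito
        )
        assert calls == []

    def test_sequenceless_insertions_dropped(self, small_mito):
        var = IndelVariant("insertion", iv(10, 11), 500, "asm4", sequence=None)
        assert call_novel_insertions([var], small_mito) == []


class TestWelch:
    def test_identical_groups_give_t0_p1(self):
        res = compare_identity_groups({"a": [90, 91, 92], "b": [90, 91, 92]})[0]
        assert res.t == 0.0
        assert res.p == 1.0
        assert res.stars == "ns"

    def test_matches_closed_form_to_1e10(self):
        x = [80.0, 81.0, 82.0, 83.0]
        y = [95.0, 96.0, 97.0, 98.5]
        res = compare_identity_groups({"x": x, "y": y})[0]
        t, df, p = welch_closed_form(x, y)
        assert res.t == pytest.approx(t, abs=1e-10)
        assert res.df == pytest.approx(df, abs=1e-10)
        assert res.p == pytest.approx(p, abs=1e-10)

    def test_unequal_sizes_and_variances(self):
        rng = np.random.default_rng(4)
        x = list(rng.normal(90, 1.0, 11))
        y = list(rng.normal(95, 4.0, 37))
        res = compare_identity_groups({"x": x, "y": y})[0]
        t, df, p = welch_closed_form(x, y)
        assert res.t == pytest.approx(t, abs=1e-10)
        assert res.df == pytest.approx(df, abs=1e-10)
        assert res.p == pytest.approx(p, abs=1e-10)

    def test_small_group_excluded(self):
        res = compare_identity_groups({"a": [1.0], "b": [5.0, 6.0], "c": [7.0, 8.0]})
        names = {(r.group_a, r.group_b) for r in res}
        assert names == {("b", "c")}

    def test_star_ladder(self):
        rng = np.random.default_rng(8)
        far = compare_identity_groups(
            {"a": list(rng.normal(0, 1, 50)), "b": list(rng.normal(10, 1, 50))}
        )[0]
        assert far.stars == "****"
        near = compare_identity_groups({"a": [1.0, 2.0, 3.0], "b": [1.1, 2.1, 3.1]})[0]
        assert near.stars == "ns"


class TestSyntheticPairTruth:
    def test_recovers_exactly_the_excised_subset(self, dimorph_fixture):
        """On an assembly pair where a known Numt subset was deleted, every
        clean deletion is called absent and everything else stays fixed."""
        from numtkit import annotate_assembly

        fx = dimorph_fixture
        loci = annotate_assembly(fx.reference, fx.mito)
        hsps = [m for l in loci if not l.unconfirmed for m in l.members]
        ids = []
        for h in hsps:
            hits = [
                t.numt_id
                for t in fx.truth
                if t.scaffold == h.nuclear.seq_name
                and h.nuclear.overlap_bp(GenomicInterval(t.scaffold, t.start, t.end)) > 0
            ]
            assert len(hits) == 1
            ids.append(hits[0])
        calls = call_absence(hsps, fx.variants, ids=ids)
        absent = {c.subject_id for c in calls if c.status.startswith("absent")}
        assert absent == fx.absent_ids | fx.large_sv_ids
        fixed = {c.subject_id for c in calls if c.status == "fixed"}
        assert fixed == {t.numt_id for t in fx.truth} - absent
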