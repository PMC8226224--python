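import random

import pytest

from scubshift.codons import CdsRecord
from scubshift.indels import (
    GAP,
    PairwiseAlignment,
    RegionClass,
    align_pair,
    classify_region_codons,
    extract_flanking_windows,
    extract_remote_regions,
    filter_eligible_indels,
    find_indels,
    regional_scub,
    remote_codon_starts,
)


def make_gapped(seq, spans):
    """Replace ungapped spans [(l, r), ...] of seq with gap columns."""
    out = list(seq)
    for l, r in spans:
        for i in range(l, r):
            out[i] = GAP
    return "".join(out)


def toy_alignment(length=600, gap_spans=(), seed=7):
    rng = random.Random(seed)
    seq = "".join(rng.choice("ACGT") for _ in range(length))
    return PairwiseAlignment(
        id_a="ra", id_b="rb", aligned_a=seq, aligned_b=make_gapped(seq, gap_spans)
    )


class TestPairwiseAlignment:
    def test_roundtrip_ungapping(self):
        aln = toy_alignment(gap_spans=[(120, 126)])
        assert aln.seq("a") == aln.aligned_a
        assert len(aln.seq("b")) == 594
        assert aln.seq("b") == aln.aligned_a[:120] + aln.aligned_a[126:]

    def test_rejects_unequal_lengths(self):
        with pytest.raises(ValueError):
            PairwiseAlignment("a", "b", "ACGT", "ACG")

    def test_rejects_double_gap_column(self):
        with pytest.raises(ValueError):
            PairwiseAlignment("a", "b", "AC-T", "AC-T")


class TestFindIndels:
    def test_single_gap_run(self):
        aln = PairwiseAlignment("a", "b", "ATGGCA---GCT", "ATGGCAAAAGCT")
        indels = find_indels(aln)
        assert len(indels) == 1
        d = indels[0]
        assert (d.col_start, d.col_end) == (6, 9)
        assert d.length_nt == 3
        assert d.gapped_side == "a"
        assert d.interval_a == (6, 6)
        assert d.interval_b == (6, 9)

    def test_gap_free(self):
        aln = PairwiseAlignment("a", "b", "ATGGCAGCT", "ATGGCAGCT")
        assert find_indels(aln) == []

    def test_one_indel_per_side(self):
        aln = PairwiseAlignment("a", "b", "A--A", "AAA-")
        indels = find_indels(aln)
        assert len(indels) == 2
        assert {d.gapped_side for d in indels} == {"a", "b"}


class TestFilterEligibleIndels:
    def test_too_close_to_start(self):
        aln = toy_alignment(300, [(30, 33)])
        indels = find_indels(aln)
        assert filter_eligible_indels(indels, aln) == []

    def test_boundary_strict_inequality(self):
        # anchored at 46 (>45) and far from the end: retained
        aln = toy_alignment(300, [(46, 49)])
        indels = find_indels(aln)
        assert len(filter_eligible_indels(indels, aln)) == 1
        # anchored exactly at 45: excluded
        aln = toy_alignment(300, [(45, 48)])
        assert filter_eligible_indels(find_indels(aln), aln) == []

    def test_too_close_to_end(self):
        # ends 42 nt before the CDS end on the ungapped side
        aln = toy_alignment(300, [(255, 258)])
        assert filter_eligible_indels(find_indels(aln), aln) == []


class TestExtractFlankingWindows:
    def test_codon_boundary_indel(self):
        aln = toy_alignment(600, [(120, 126)])
        indels = find_indels(aln)
        w = extract_flanking_windows(aln, indels[0], indels)
        assert w.span5["a"] == (75, 120)
        assert w.span3["a"] == (126, 171)  # a-coords: indel occupies [120,126)
        assert w.span5["b"] == (75, 120)
        assert w.span3["b"] == (120, 165)  # b-coords: zero-width point at 120
        assert not w.truncated["a"] and not w.truncated["b"]
        assert len(w.codons(aln, "a", "flank5")) == 15
        assert len(w.codons(aln, "b", "flank3")) == 15

    def test_mid_codon_indel_drops_broken_codon(self):
        aln = toy_alignment(600, [(121, 127)])
        indels = find_indels(aln)
        w = extract_flanking_windows(aln, indels[0], indels)
        # a side: indel spans [121,127); codon [120,123) is broken
        assert w.span5["a"] == (75, 120)
        assert w.span3["a"] == (129, 174)
        # b side: deletion point at 121 breaks codon [120,123) of b
        assert w.span5["b"] == (75, 120)
        assert w.span3["b"] == (123, 168)

    def test_close_indels_exclude_inter_segment(self):
        # segments of 80 nt (<90) between the two indels on both sides
        aln = toy_alignment(600, [(120, 123), (203, 206)])
        indels = find_indels(aln)
        w1 = extract_flanking_windows(aln, indels[0], indels)
        w2 = extract_flanking_windows(aln, indels[1], indels)
        for side in ("a", "b"):
            assert w1.span3[side] is None
            assert w2.span5[side] is None
            assert w1.span5[side] is not None
            assert w2.span3[side] is not None

    def test_exactly_90_nt_segment_keeps_both_flanks(self):
        aln = toy_alignment(600, [(120, 123), (213, 216)])
        indels = find_indels(aln)
        w1 = extract_flanking_windows(aln, indels[0], indels)
        w2 = extract_flanking_windows(aln, indels[1], indels)
        assert w1.span3["a"] == (123, 168)
        assert w2.span5["a"] == (168, 213)

    def test_flank_and_remote_are_disjoint(self):
        aln = toy_alignment(600, [(121, 127)])
        indels = find_indels(aln)
        w = extract_flanking_windows(aln, indels[0], indels)
        for side in ("a", "b"):
            flank_nt = set()
            for span in (w.span5[side], w.span3[side]):
                flank_nt.update(range(*span))
            remote_nt = set()
            for s in remote_codon_starts(aln, indels, side):
                remote_nt.update((s, s + 1, s + 2))
            assert not (flank_nt & remote_nt)


class TestRemoteRegions:
    def test_gap_free_whole_cds_is_remote(self):
        aln = toy_alignment(300, [])
        remote = extract_remote_regions(aln, find_indels(aln))
        assert len(remote["a"]) == 100
        assert len(remote["b"]) == 100

    def test_single_indel_removes_collar(self):
        aln = toy_alignment(600, [(300, 303)])
        starts = remote_codon_starts(aln, find_indels(aln), "a")
        # naive predicate: distance of every nt > 45 from the span [300,303)
        def dist(q):
            if 300 <= q < 303:
                return 0
            return 300 - q if q < 300 else q - 303 + 1

        expected = [
            s
            for s in range(0, 598, 3)
            if all(dist(q) > 45 for q in (s, s + 1, s + 2))
        ]
        assert starts == expected

    def test_brute_force_oracle_600nt(self):
        """Window/remote coordinates vs independent enumeration (one indel)."""
        aln = toy_alignment(600, [(301, 307)])
        indels = find_indels(aln)
        eligible = filter_eligible_indels(indels, aln)
        assert len(eligible) == 1
        w = extract_flanking_windows(aln, eligible[0], indels)

        for side in ("a", "b"):
            l, r = eligible[0].interval(side)
            L = len(aln.seq(side))
            complete = [s for s in range(0, L - 2, 3) if s + 3 <= l or s >= r]
            # the 15 complete codons immediately 5' / 3' of the indel
            flank5 = [s for s in complete if s + 3 <= l][-15:]
            flank3 = [s for s in complete if s >= r][:15]
            assert list(range(*w.span5[side], 3)) == flank5
            assert list(range(*w.span3[side], 3)) == flank3

            def dist(q):
                if l <= q < r:
                    return 0
                return l - q if q < l else q - r + 1

            expected_remote = [
                s
                for s in range(0, L - 2, 3)
                if all(dist(q) > 45 for q in (s, s + 1, s + 2))
            ]
            assert remote_codon_starts(aln, indels, side) == expected_remote


class TestRegionalScub:
    def test_identical_inputs_identical_frequencies(self):
        aln = toy_alignment(600, [(120, 126)])
        regions = classify_region_codons([aln])
        scub_a = regional_scub(regions["a"])
        # sides differ only by the deleted segment; compare a with itself
        assert scub_a[RegionClass.WHOLE] is not None
        regions2 = classify_region_codons([aln])
        assert regional_scub(regions2["a"]) == scub_a

    def test_two_sides_is_flank_sum(self):
        aln = toy_alignment(900, [(200, 206), (500, 503)])
        regions = classify_region_codons([aln])
        for side in ("a", "b"):
            c5 = regions[side].codons[RegionClass.FLANK5]
            c3 = regions[side].codons[RegionClass.FLANK3]
            both = regions[side].codons[RegionClass.TWO_SIDES]
            assert sorted(both) == sorted(c5 + c3)

    def test_empty_region_is_none(self):
        aln = toy_alignment(300, [])  # no indels -> no flanks
        regions = classify_region_codons([aln])
        scub = regional_scub(regions["a"])
        assert scub[RegionClass.FLANK5] is None
        assert scub[RegionClass.TWO_SIDES] is None
        assert scub[RegionClass.REMOTE] is not None


class TestAlignPair:
    def test_identity(self):
        a = CdsRecord(id="a", sequence="ATGGCAGCT")
        b = CdsRecord(id="b", sequence="ATGGCAGCT")
        aln = align_pair(a, b)
        assert aln.aligned_a == aln.aligned_b == "ATGGCAGCT"
        assert find_indels(aln) == []

    def test_single_gap_run(self):
        a = CdsRecord(id="a", sequence="ATGGCAAAAGCTGCT")
        b = CdsRecord(id="b", sequence="ATGGCAGCTGCT")
        aln = align_pair(a, b)
        assert aln.seq("a") == a.sequence
        assert aln.seq("b") == b.sequence
        indels = find_indels(aln)
        assert len(indels) == 1
        assert indels[0].length_nt == 3
        assert indels[0].gapped_side == "b"

    def test_deterministic(self):
        a = CdsRecord(id="a", sequence="ATGGCAAAAGCTTTTGCA")
        b = CdsRecord(id="b", sequence="ATGGCAGCTTTTGCA")
        aln1 = align_pair(a, b)
        aln2 = align_pair(a, b)
        assert aln1.aligned_a == aln2.aligned_a
        assert aln1.aligned_b == aln2.aligned_b
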