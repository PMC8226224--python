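import pytest
from scipy import stats as sps

from scubshift.codons import STANDARD_CODE, CodonCounts, extract_codons, total_ending_frequencies
from scubshift.indels import filter_eligible_indels, find_indels
from scubshift.partitions import WHEAT_CHROMOSOMES
from scubshift.simulate import (
    ConfigError,
    MutationParams,
    assign_chromosomes,
    generate_ancestral_cds,
    mutate_genome,
)


class TestGenerateAncestralCds:
    def test_deterministic(self):
        a = generate_ancestral_cds(20, 50, seed=11)
        b = generate_ancestral_cds(20, 50, seed=11)
        assert [(r.id, r.sequence) for r in a] == [(r.id, r.sequence) for r in b]
        c = generate_ancestral_cds(20, 50, seed=12)
        assert [r.sequence for r in a] != [r.sequence for r in c]

    def test_structure(self):
        for rec in generate_ancestral_cds(5, 30, seed=0):
            assert rec.sequence.startswith("ATG")
            assert rec.sequence.endswith("TAA")
            codons = extract_codons(rec)
            assert len(codons) == 32
            body = codons[1:-1]
            assert all(c in STANDARD_CODE.sc_set for c in body)

    def test_zero_records(self):
        assert generate_ancestral_cds(0, 30, seed=0) == []

    def test_length_range(self):
        lengths = {
            len(r.sequence)
            for r in generate_ancestral_cds(50, (10, 20), seed=3)
        }
        assert lengths <= {3 * n + 6 for n in range(10, 21)}
        assert len(lengths) > 3

    def test_uniform_usage_matches_multiplicity_shares(self):
        """With uniform SC usage, ending frequencies equal each ending's
        share of the 59 codons: A 14/59, T 16/59, C 16/59, G 13/59."""
        usage = {c: 1 / 59 for c in STANDARD_CODE.sc_set}
        recs = generate_ancestral_cds(10, 10000, codon_usage=usage, seed=5)
        counts = sum(
            (CodonCounts.from_codons(extract_codons(r)[1:-1]) for r in recs),
            CodonCounts(),
        )
        ef = total_ending_frequencies(counts)
        assert ef.f_A == pytest.approx(14 / 59, abs=0.01)
        assert ef.f_T == pytest.approx(16 / 59, abs=0.01)
        assert ef.f_C == pytest.approx(16 / 59, abs=0.01)
        assert ef.f_G == pytest.approx(13 / 59, abs=0.01)

    def test_default_usage_is_cg_dominant(self):
        recs = generate_ancestral_cds(10, 2000, seed=6)
        counts = sum(
            (CodonCounts.from_codons(extract_codons(r)) for r in recs), CodonCounts()
        )
        ef = total_ending_frequencies(counts)
        assert ef.f_C + ef.f_G > ef.f_A + ef.f_T

    def test_bad_usage_rejected(self):
        usage = {c: 1 / 59 for c in STANDARD_CODE.sc_set}
        usage["GCA"] += 0.01
        with pytest.raises(ConfigError, match="sums to"):
            generate_ancestral_cds(1, 10, codon_usage=usage, seed=0)
        with pytest.raises(ConfigError, match="non-SC"):
            generate_ancestral_cds(1, 10, codon_usage={"ATG": 1.0}, seed=0)


class TestMutateGenome:
    def test_identity_with_zero_rates(self):
        anc = generate_ancestral_cds(10, 50, seed=1)
        res = mutate_genome(anc, MutationParams(sub_rate=0.0, indel_rate=0.0, seed=1))
        assert [r.sequence for r in res.derived] == [r.sequence for r in anc]
        assert all(
            not t.substitutions and not t.indels for t in res.truth.records.values()
        )

    def test_truth_replay_reproduces_derived(self):
        anc = generate_ancestral_cds(30, 100, seed=2)
        params = MutationParams(
            sub_rate=0.02, cpg_multiplier=5.0, indel_rate=1.0, seed=2
        )
        res = mutate_genome(anc, params)
        replayed = res.truth.replay(anc)
        for rec in res.derived:
            assert replayed[rec.id] == rec.sequence

    def test_truth_json_roundtrip(self, tmp_path):
        anc = generate_ancestral_cds(5, 60, seed=3)
        res = mutate_genome(anc, MutationParams(sub_rate=0.05, indel_rate=0.5, seed=3))
        path = tmp_path / "truth.json"
        res.truth.to_json(path)
        from scubshift.simulate import SyntheticTruth

        loaded = SyntheticTruth.from_json(path)
        assert loaded.replay(anc) == res.truth.replay(anc)
        assert loaded.params == res.truth.params

    def test_alignment_gap_exact(self):
        anc = generate_ancestral_cds(20, 80, seed=4)
        res = mutate_genome(anc, MutationParams(sub_rate=0.01, indel_rate=1.0, seed=4))
        for rec, aln in zip(anc, res.alignments):
            assert aln.seq("a") == rec.sequence
        derived_by_id = {r.id: r for r in res.derived}
        for aln in res.alignments:
            assert aln.seq("b") == derived_by_id[aln.id_b].sequence

    def test_indels_eligible_by_construction(self):
        anc = generate_ancestral_cds(50, 200, seed=5)
        res = mutate_genome(anc, MutationParams(indel_rate=1.5, seed=5))
        n_indels = 0
        for aln in res.alignments:
            indels = find_indels(aln)
            assert filter_eligible_indels(indels, aln) == indels
            n_indels += len(indels)
        assert n_indels > 20

    def test_indel_lengths_multiple_of_3(self):
        anc = generate_ancestral_cds(30, 150, seed=6)
        res = mutate_genome(anc, MutationParams(indel_rate=1.0, seed=6))
        for t in res.truth.records.values():
            for ev in t.indels:
                assert ev.length % 3 == 0

    def test_substitutions_synonymous_by_default(self):
        anc = generate_ancestral_cds(20, 200, seed=7)
        res = mutate_genome(anc, MutationParams(sub_rate=0.05, seed=7))
        anc_by_id = {r.id: r for r in anc}
        der_by_id = {r.id: r for r in res.derived}
        aa = STANDARD_CODE.codon_to_aa
        for rid in anc_by_id:
            a = extract_codons(anc_by_id[rid])
            d = extract_codons(der_by_id[rid])
            assert [aa[c] for c in a] == [aa[c] for c in d]
        assert res.truth.n_rejected > 0

    def test_neutral_cpg_rate_is_context_free(self):
        """With multiplier 1, substitution rates in CpG vs non-CpG context are
        proportional to context frequencies (binomial test on truth events)."""
        anc = generate_ancestral_cds(100, 500, seed=8)
        # selection is disabled so acceptance cannot distort context rates
        res = mutate_genome(
            anc,
            MutationParams(
                sub_rate=0.03, cpg_multiplier=1.0, reject_nonsynonymous=False, seed=8
            ),
        )
        n_cpg_sites = 0
        n_sites = 0
        for rec in anc:
            s = rec.sequence
            n_sites += len(s)
            for i, ch in enumerate(s[:-1]):
                if ch == "C" and s[i + 1] == "G":
                    n_cpg_sites += 2
        hits = [
            ev
            for t in res.truth.records.values()
            for ev in t.substitutions
        ]
        cpg_hits = 0
        for rec in anc:
            s = rec.sequence
            for ev in res.truth.records[rec.id].substitutions:
                p = ev.pos
                in_cpg = (s[p] == "C" and p + 1 < len(s) and s[p + 1] == "G") or (
                    s[p] == "G" and p > 0 and s[p - 1] == "C"
                )
                cpg_hits += in_cpg
        res_binom = sps.binomtest(cpg_hits, len(hits), n_cpg_sites / n_sites)
        assert res_binom.pvalue > 0.001

    def test_rate_validation(self):
        with pytest.raises(ConfigError):
            MutationParams(sub_rate=1.5)
        with pytest.raises(ConfigError):
            MutationParams(cpg_multiplier=0.5)
        with pytest.raises(ConfigError):
            MutationParams(indel_lengths=())


class TestAssignChromosomes:
    def test_deterministic(self):
        ids = [f"u{i}" for i in range(100)]
        a = assign_chromosomes(ids, seed=1)
        b = assign_chromosomes(ids, seed=1)
        assert a.equals(b)

    def test_all_unmapped(self):
        df = assign_chromosomes(["u1", "u2"], unmapped_frac=1.0, seed=0)
        assert (df["chromosome"] == "unmapped").all()

    def test_roughly_uniform(self):
        ids = [f"u{i}" for i in range(21000)]
        df = assign_chromosomes(ids, unmapped_frac=0.0, seed=2)
        counts = df["chromosome"].value_counts()
        assert set(counts.index) == set(WHEAT_CHROMOSOMES)
        assert (abs(counts - 1000) < 110).all()  # ~3.5 sigma at n=21000

    def test_invalid_introgressed_name(self):
        with pytest.raises(ConfigError):
            assign_chromosomes(["u1"], introgressed_set={"9Z"}, seed=0)
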