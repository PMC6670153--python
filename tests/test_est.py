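import numpy as np
import pytest

from conftest import random_dna
from intronprom.core import GenomicRegion, reverse_complement
from intronprom.est import (
    GAP,
    ESTRecord,
    MultipleAlignment,
    Scheme,
    build_msa,
    call_consensus,
    local_align,
    match_consensus,
    pairwise_align,
    score_aligned_pair,
    select_ests,
    to_transcript_orientation,
)
from oracles import local_score_bruteforce, overlap_score_bruteforce


def est(acc, start, end, strand="+", seq=None, chrom="chr21"):
    return ESTRecord(acc, chrom, start, end, strand, seq or "A" * (end - start))


class TestSelectEsts:
    def test_accession_list_returns_exactly_those(self):
        table = [est(f"E{i}", i * 10, i * 10 + 5) for i in range(10)]
        picked = select_ests(table, accessions=["E3", "E7", "E1"])
        assert [e.accession for e in picked] == ["E3", "E7", "E1"]

    def test_missing_accessions_listed_in_error(self):
        with pytest.raises(KeyError, match="NOPE"):
            select_ests([est("E0", 0, 5)], accessions=["E0", "NOPE"])

    def test_strand_filter_can_empty(self):
        table = [est("E0", 0, 5, "+"), est("E1", 5, 9, "+")]
        reg = GenomicRegion("chr21", 0, 100, "r")
        assert select_ests(table, region=reg, strand="-") == []

    def test_overlap_filter_matches_bruteforce(self, rng):
        reg = GenomicRegion("chr21", 1000, 2000, "r")
        table = []
        for i in range(60):
            s = int(rng.integers(0, 2900))
            table.append(est(f"E{i}", s, s + int(rng.integers(1, 300)), str(rng.choice(["+", "-"]))))
        got = select_ests(table, region=reg, strand="+")
        expected = [
            e
            for e in table
            if e.strand == "+" and e.start < reg.end and e.end > reg.start
        ]
        assert got == expected


class TestPairwiseAlign:
    def test_identical_sequences_align_without_gaps(self):
        a, b, score = pairwise_align("ACGTACGT", "ACGTACGT")
        assert (a, b) == ("ACGTACGT", "ACGTACGT")
        assert score == 8

    def test_trailing_end_gap_is_free(self):
        a, b, score = pairwise_align("ACGT", "ACG")
        assert score == 3
        assert (a, b) == ("ACGT", "ACG-")

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            pairwise_align("", "ACGT")

    def test_degapped_rows_recover_inputs(self, rng):
        for _ in range(50):
            a = random_dna(rng, int(rng.integers(1, 30)))
            b = random_dna(rng, int(rng.integers(1, 30)))
            ra, rb, _ = pairwise_align(a, b)
            assert ra.replace(GAP, "") == a
            assert rb.replace(GAP, "") == b
            assert len(ra) == len(rb)

    def test_score_matches_matching_enumeration_oracle(self, rng):
        for _ in range(100):
            a = random_dna(rng, int(rng.integers(1, 8)))
            b = random_dna(rng, int(rng.integers(1, 8)))
            _, _, score = pairwise_align(a, b)
            assert score == overlap_score_bruteforce(a, b)

    def test_score_matches_biopython_overlap_aligner(self, rng):
        from Bio import Align

        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 1
        aligner.mismatch_score = -1
        aligner.open_gap_score = -2
        aligner.extend_gap_score = -2
        try:
            aligner.end_insertion_score = 0
            aligner.end_deletion_score = 0
        except AttributeError:
            aligner.target_end_gap_score = 0
            aligner.query_end_gap_score = 0
        for _ in range(60):
            a = random_dna(rng, int(rng.integers(1, 25)))
            b = random_dna(rng, int(rng.integers(1, 25)))
            _, _, score = pairwise_align(a, b)
            assert score == max(aligner.score(a, b), 0)

    def test_reported_alignment_scores_its_own_score(self, rng):
        for _ in range(60):
            a = random_dna(rng, int(rng.integers(1, 20)))
            b = random_dna(rng, int(rng.integers(1, 20)))
            ra, rb, score = pairwise_align(a, b)
            assert score_aligned_pair(ra, rb) == score


class TestBuildMsa:
    def test_identical_rows_stay_gap_free(self):
        msa = build_msa(["ACGTAC"] * 4)
        assert msa.rows == ["ACGTAC"] * 4

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            build_msa(["ACGT"])

    def test_staggered_exact_fragments_tile_the_template(self, rng):
        template = random_dna(rng, 120)
        frags = [template[s : s + 60] for s in (0, 20, 40, 60)]
        msa = build_msa(frags)
        assert msa.length == 120
        # each row occupies its own offset window, gap-free inside it
        for row, offset in zip(msa.rows, (0, 20, 40, 60)):
            assert row == GAP * offset + template[offset : offset + 60] + GAP * (60 - offset)

    def test_alignment_at_least_as_long_as_longest_input(self, rng):
        seqs = [random_dna(rng, int(rng.integers(5, 40))) for _ in range(5)]
        msa = build_msa(seqs)
        assert msa.length >= max(len(s) for s in seqs)

    def test_degapping_recovers_every_input(self, rng):
        for _ in range(25):
            seqs = [random_dna(rng, int(rng.integers(3, 25))) for _ in range(int(rng.integers(2, 6)))]
            msa = build_msa(seqs)
            for k, s in enumerate(seqs):
                assert msa.degapped(k) == s

    def test_center_rows_keep_optimal_pairwise_score(self, rng):
        # projecting any row against the center reproduces the optimal
        # pairwise alignment score (center-star guarantee)
        for _ in range(15):
            seqs = [random_dna(rng, int(rng.integers(8, 30))) for _ in range(4)]
            msa = build_msa(seqs)
            c = msa.center_index
            for k in range(len(seqs)):
                if k == c:
                    continue
                _, _, best = pairwise_align(seqs[c], seqs[k])
                assert score_aligned_pair(msa.rows[c], msa.rows[k]) == best


class TestCallConsensus:
    def test_unanimous_columns_full_support(self):
        msa = MultipleAlignment(ids=["a", "b", "c"], rows=["ACG", "ACG", "ACG"])
        res = call_consensus(msa)
        assert res.sequence == "ACG"
        assert res.support == [1.0] * 3
        assert res.depth == [3] * 3

    def test_even_split_column_is_n(self):
        msa = MultipleAlignment(ids=list("wxyz"), rows=["A", "A", "C", "C"])
        assert call_consensus(msa).sequence == "N"

    def test_weak_majority_below_support_is_n(self):
        rows = ["A", "A", "C", "G"]
        msa = MultipleAlignment(ids=list("wxyz"), rows=rows)
        assert call_consensus(msa, min_support=0.6).sequence == "N"
        assert call_consensus(msa, min_support=0.5).sequence == "A"

    def test_shallow_columns_dropped(self):
        msa = MultipleAlignment(ids=["a", "b"], rows=["AC-", "A--"])
        res = call_consensus(msa, min_depth=2)
        assert res.sequence == "A"
        assert res.columns == [0]

    def test_error_free_fragments_give_exact_template_consensus(self, rng):
        template = random_dna(rng, 100)
        frags = [template[s : s + 60] for s in (0, 10, 20, 30, 40)]
        res = call_consensus(build_msa(frags), min_depth=2)
        assert res.sequence in template  # contiguous covered span

    def test_noisy_fragments_recover_template_at_high_identity(self, rng):
        template = random_dna(rng, 600)
        frags = []
        for _ in range(8):
            ln = 350
            s = int(rng.integers(0, 600 - ln + 1))
            chars = list(template[s : s + ln])
            for i in np.flatnonzero(rng.random(ln) < 0.01):
                chars[i] = rng.choice([b for b in "ACGT" if b != chars[i]])
            frags.append("".join(chars))
        res = call_consensus(build_msa(frags), min_depth=2, min_support=0.6)
        match = match_consensus(res.sequence, [("template", template)])
        assert match.identity >= 0.99


class TestMatchConsensus:
    def test_exact_substring_identity_one(self, rng):
        t = random_dna(rng, 200)
        match = match_consensus(t[50:120], [("t1", t), ("t2", random_dna(rng, 200))])
        assert match.transcript_id == "t1"
        assert match.identity == 1.0
        assert (match.target_start, match.target_end) == (50, 120)

    def test_constructed_negative_reports_low_identity(self, rng):
        # consensus over A/C, transcripts over G/T: nothing can match well
        consensus = random_dna(rng, 40, alphabet="AC")
        match = match_consensus(consensus, [("bg", random_dna(rng, 300, alphabet="GT"))],
                                min_identity=0.5)
        assert match.identity < 0.5 or match.score <= 2

    def test_local_score_matches_matching_enumeration_oracle(self, rng):
        for _ in range(100):
            a = random_dna(rng, int(rng.integers(1, 8)))
            b = random_dna(rng, int(rng.integers(1, 8)))
            _, _, score, _, _ = local_align(a, b)
            assert score == local_score_bruteforce(a, b)

    def test_empty_transcript_set_rejected(self):
        with pytest.raises(ValueError):
            match_consensus("ACGT", [])


def test_minus_strand_ests_reoriented_for_alignment():
    rec = ESTRecord("E", "chr21", 0, 4, "-", "ACGT")
    assert to_transcript_orientation(rec) == reverse_complement("ACGT")
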