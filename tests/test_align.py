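import random

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from oracles import overlap_components, rc, sw_affine, sw_affine_protein, translate_codons
from tetrack.align import (
    HomologyHit,
    SubjectIndex,
    deduplicate_queries,
    filter_significant,
    search_dna_vs_dna,
    search_protein_vs_dna,
    translate_six_frames,
)
from tetrack.core import PipelineParams, ProteinQuery, SequenceRecord, revcomp


def _random_dna(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


def _mutate_copy(rng, seq, n_subs, n_indels):
    out = list(seq)
    for _ in range(n_subs):
        i = rng.randrange(len(out))
        out[i] = rng.choice("ACGT")
    for _ in range(n_indels):
        i = rng.randrange(len(out))
        if rng.random() < 0.5:
            out.insert(i, rng.choice("ACGT"))
        elif len(out) > 2:
            del out[i]
    return "".join(out)


class TestSixFrames:
    def test_standard_code(self):
        frames = dict(translate_six_frames("ATGAAATAA"))
        assert frames[1] == "MK*"

    def test_reverse_frame_mirrors_forward(self):
        seq = "ATGGCCATTGTAATG"
        fwd = dict(translate_six_frames(seq))
        rev = dict(translate_six_frames(revcomp(seq)))
        assert fwd[-1] == rev[1]

    def test_all_frames_against_codon_oracle(self):
        rng = random.Random(5)
        seq = _random_dna(rng, 300)
        for frame, aa in translate_six_frames(seq):
            template = seq if frame > 0 else rc(seq)
            sub = template[abs(frame) - 1 :]
            assert aa == translate_codons(sub)


class TestDnaSearch:
    def test_self_hit_full_length(self, params):
        rng = random.Random(2)
        q = SequenceRecord("q", _random_dna(rng, 500))
        h = search_dna_vs_dna(q, SequenceRecord("s", q.seq), params)[0]
        assert (h.q_start, h.q_end, h.s_start, h.s_end) == (0, 500, 0, 500)
        assert h.percent_identity == 100.0
        assert h.strand == "+"

    def test_revcomp_hit_on_minus_strand(self, params):
        rng = random.Random(3)
        q = SequenceRecord("q", _random_dna(rng, 400))
        h = search_dna_vs_dna(q, SequenceRecord("s", revcomp(q.seq)), params)[0]
        assert h.strand == "-"
        assert (h.q_start, h.q_end) == (0, 400)
        assert (h.s_start, h.s_end) == (0, 400)

    def test_scores_equal_smith_waterman_on_small_pairs(self, params):
        """Seed-and-extend optimum equals the full-matrix affine-gap DP
        on homologous pairs up to 300 bp (and never exceeds it)."""
        rng = random.Random(11)
        agree = 0
        for _ in range(50):
            core = _random_dna(rng, rng.randint(60, 220))
            # keep a 30-bp block conserved so the pair always shares a seed
            q = core[:30] + _mutate_copy(rng, core[30:], rng.randint(0, 12), rng.randint(0, 3))
            s = _random_dna(rng, rng.randint(0, 40)) + core + _random_dna(rng, rng.randint(0, 40))
            hits = search_dna_vs_dna(SequenceRecord("q", q), SequenceRecord("s", s), params)
            got = hits[0].raw_score if hits else 0
            expected = sw_affine(q, s)
            assert got <= expected
            if got == expected:
                agree += 1
        assert agree == 50

    def test_identity_consistent_with_alignment(self, params):
        rng = random.Random(13)
        core = _random_dna(rng, 200)
        q = _mutate_copy(rng, core, 10, 0)
        hits = search_dna_vs_dna(SequenceRecord("q", q), SequenceRecord("s", core), params)
        h = hits[0]
        n_ident = sum(1 for a, b in zip(q[h.q_start : h.q_end], core[h.s_start : h.s_end]) if a == b)
        assert h.percent_identity == pytest.approx(100.0 * n_ident / h.aln_len, abs=0.01)

    def test_evalue_scales_with_subject_length(self, params):
        rng = random.Random(17)
        core = _random_dna(rng, 150)
        pad = _random_dna(rng, 1000)
        q = SequenceRecord("q", core)
        e1 = search_dna_vs_dna(q, SequenceRecord("s", core + pad), params)[0].e_value
        e2 = search_dna_vs_dna(q, SequenceRecord("s", core + pad + _random_dna(rng, 1150)), params)[0].e_value
        assert e2 == pytest.approx(2 * e1, rel=0.01)

    def test_evalue_decreases_with_score(self, params):
        rng = random.Random(19)
        s = SequenceRecord("s", _random_dna(rng, 2000))
        short = SequenceRecord("q1", s.seq[100:200])
        long = SequenceRecord("q2", s.seq[100:400])
        e_short = search_dna_vs_dna(short, s, params)[0].e_value
        e_long = search_dna_vs_dna(long, s, params)[0].e_value
        assert e_long < e_short


class TestProteinSearch:
    def test_embedded_orf_found_at_full_identity(self, params):
        rng = random.Random(23)
        aa = "M" + "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(120))
        codon = {c: [k for k, v in _CODON.items() if v == c][0] for c in set(aa)}
        orf = "".join(codon[c] for c in aa)
        subject = SequenceRecord("s", _random_dna(rng, 301) + orf + _random_dna(rng, 200))
        q = ProteinQuery("tpase", aa, "Mutator")
        hits = search_protein_vs_dna(q, subject, params)
        assert hits, "ORF not found"
        h = hits[0]
        assert h.percent_identity == 100.0
        assert h.frame == 2  # offset 301 => frame +2
        assert h.s_start == 301 and h.s_end == 301 + len(orf)

    def test_unrelated_subject_yields_nothing_significant(self, params):
        rng = random.Random(29)
        q = ProteinQuery("tpase", "MKLVDE" * 30, "hAT")
        subject = SequenceRecord("s", _random_dna(rng, 2000))
        assert filter_significant(search_protein_vs_dna(q, subject, params), params) == []

    def test_scores_equal_protein_sw_oracle(self, params):
        """On constructed in-frame cases the reported raw score equals a
        protein-space Smith-Waterman on the correct frame."""
        b62 = substitution_matrices.load("BLOSUM62")
        rng = random.Random(31)
        for _ in range(20):
            aa = "M" + "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(rng.randint(50, 90)))
            codon = {c: [k for k, v in _CODON.items() if v == c][0] for c in set(aa)}
            orf = "".join(codon[c] for c in aa)
            subject = SequenceRecord("s", orf + _random_dna(rng, 60))
            hits = search_protein_vs_dna(ProteinQuery("p", aa, "CACTA"), subject, params)
            assert hits
            frame_aa = dict(translate_six_frames(subject.seq))[1]
            assert hits[0].raw_score == sw_affine_protein(aa, frame_aa, b62)


_CODON = {
    "GCT": "A", "TGT": "C", "GAT": "D", "GAA": "E", "TTT": "F", "GGT": "G",
    "CAT": "H", "ATT": "I", "AAA": "K", "CTT": "L", "ATG": "M", "AAT": "N",
    "CCT": "P", "CAA": "Q", "CGT": "R", "TCT": "S", "ACT": "T", "GTT": "V",
    "TGG": "W", "TAT": "Y",
}


def _hit(qid, sid="chr1", s_start=0, s_end=100, e=1e-30, aln=100, bits=100.0):
    return HomologyHit(
        query_id=qid, subject_id=sid, q_start=0, q_end=aln,
        s_start=s_start, s_end=s_end, strand="+", frame=None, aln_len=aln,
        percent_identity=99.0, raw_score=aln * 2, bit_score=bits, e_value=e,
    )


class TestSignificanceFilter:
    @pytest.mark.parametrize(
        "e,length,kept",
        [
            (1e-12, 60, True),   # passes both published thresholds
            (1e-9, 200, False),  # fails the E-value rule
            (1e-20, 50, False),  # matched region must exceed 50 bp
            (1e-20, 51, True),
        ],
    )
    def test_evalue_and_length_rules(self, params, e, length, kept):
        hits = [_hit("q", e=e, aln=length, s_end=length)]
        assert bool(filter_significant(hits, params)) is kept

    def test_translated_hits_count_three_nt_per_column(self, params):
        h = HomologyHit(
            query_id="p", subject_id="t", q_start=0, q_end=20, s_start=0, s_end=60,
            strand="+", frame=1, aln_len=20, percent_identity=100.0,
            raw_score=100, bit_score=80.0, e_value=1e-20,
        )
        assert filter_significant([h], params) == [h]  # 60 nt > 50


class TestDeduplication:
    def test_disjoint_queries_stay_separate(self):
        hits = [_hit("a", s_start=0, s_end=100), _hit("b", s_start=5000, s_end=5100)]
        assert len(deduplicate_queries(hits)) == 2

    def test_identical_loci_collapse(self):
        hits = [_hit("a", e=1e-40), _hit("b", e=1e-35)]
        reps = deduplicate_queries(hits)
        assert len(reps) == 1
        assert reps[0].query_id == "a"  # best E-value represents the cluster

    def test_clustering_matches_bruteforce_components(self):
        rng = random.Random(37)
        hits = []
        for i in range(30):
            anchor = rng.choice([0, 2000, 4000, 6000])
            start = anchor + rng.randint(0, 15)
            hits.append(_hit(f"q{i:02d}", s_start=start, s_end=start + 400, e=10.0 ** -rng.randint(20, 60)))
        reps = deduplicate_queries(hits)
        ivs = [(h.subject_id, h.s_start, h.s_end) for h in hits]
        comps = overlap_components(ivs)
        assert len(reps) == len(comps)


class TestSubjectIndex:
    def test_index_reuse_matches_fresh_search(self, params):
        rng = random.Random(41)
        subjects = [SequenceRecord(f"s{i}", _random_dna(rng, 3000)) for i in range(3)]
        q = SequenceRecord("q", subjects[1].seq[500:900])
        idx = SubjectIndex(subjects, params.word_size)
        h1 = search_dna_vs_dna(q, idx, params)
        h2 = search_dna_vs_dna(q, subjects, params)
        assert h1 == h2
        assert h1[0].subject_id == "s1"
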