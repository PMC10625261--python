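import random

import pytest

from oracles import ltr_scan, polya_scan, rc, tir_scan, tsd_scan
from tetrack.align import HomologyHit, filter_significant, search_dna_vs_dna
from tetrack.core import Interval, PipelineParams, SequenceRecord
from tetrack.boundaries import (
    CandidateLocus,
    StructuralFeatures,
    TsdCandidate,
    classify_superfamily,
    define_element,
    extract_locus,
    find_ltr_pair,
    find_polya,
    find_tir,
    find_tsd,
)
from tetrack.simulate import FamilySpec, build_reference_element, simulate_genome


def _rand(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


def _mk_hit(chrom, start, end, strand="+", bits=500.0):
    return HomologyHit(
        query_id="q", subject_id=chrom, q_start=0, q_end=end - start,
        s_start=start, s_end=end, strand=strand, frame=None,
        aln_len=end - start, percent_identity=100.0, raw_score=2 * (end - start),
        bit_score=bits, e_value=1e-60,
    )


class TestExtractLocus:
    def test_window_arithmetic(self, params):
        rng = random.Random(1)
        genome = [SequenceRecord("chr1", _rand(rng, 200_000))]
        loc = extract_locus(genome, _mk_hit("chr1", 50_000, 55_000), params)
        assert (loc.window.start, loc.window.end) == (40_000, 65_000)

    def test_left_clipping(self, params):
        rng = random.Random(2)
        genome = [SequenceRecord("chr1", _rand(rng, 50_000))]
        loc = extract_locus(genome, _mk_hit("chr1", 2_000, 4_000), params)
        assert (loc.window.start, loc.window.end) == (0, 14_000)

    def test_window_seq_equals_direct_slice(self, params):
        rng = random.Random(3)
        genome = [SequenceRecord("chr1", _rand(rng, 60_000))]
        loc = extract_locus(genome, _mk_hit("chr1", 20_000, 22_000), params)
        assert loc.window_seq == genome[0].seq[loc.window.start : loc.window.end]

    def test_off_chromosome_hit_errors(self, params):
        rng = random.Random(4)
        genome = [SequenceRecord("chr1", _rand(rng, 1_000))]
        with pytest.raises(ValueError):
            extract_locus(genome, _mk_hit("chr1", 500, 2_000), params)
        with pytest.raises(ValueError):
            extract_locus(genome, _mk_hit("chrX", 0, 100), params)


class TestFindTsd:
    def test_constructed_repeat_found(self, params):
        rng = random.Random(1)
        body = _rand(rng, 300)
        locus = _rand(rng, 45) + "AACCG" + body + "AACCG" + _rand(rng, 45)
        a, b = 50, 350
        top = find_tsd(locus, a, b, params)[0]
        assert top.seq == "AACCG"
        assert (top.body_start, top.body_end, top.jitter) == (a, b, 0)

    def test_no_repeat_no_candidates(self, params):
        rng = random.Random(2)
        # homopolymer flanks share nothing with each other or the body
        locus = "A" * 40 + _rand(rng, 100) + "C" * 40
        assert find_tsd(locus, 40, 140, params) == []

    def test_matches_bruteforce_enumeration(self, params):
        rng = random.Random(7)
        for _ in range(25):
            tsd = _rand(rng, rng.randint(2, 12))
            body = _rand(rng, rng.randint(40, 120))
            locus = _rand(rng, 30) + tsd + body + tsd + _rand(rng, 30)
            a, b = 30 + len(tsd), 30 + len(tsd) + len(body)
            got = {(c.seq, c.body_start, c.body_end) for c in find_tsd(locus, a, b, params)}
            expected = tsd_scan(
                locus, a, b, params.tsd_len_min, params.tsd_len_max, params.boundary_jitter
            )
            assert got == expected


class TestFindLtr:
    def test_identical_terminal_repeats(self, params):
        el = build_reference_element(FamilySpec("f", "LTR", 2000, ltr_len=100, tsd_len=5), seed=1)
        call = find_ltr_pair(el.record.seq, (0, 2000), params)
        assert call is not None
        assert call.length == 100 and call.identity == 100.0
        assert call.left == (0, 100) and call.right == (1900, 2000)

    def test_tir_element_has_no_ltr_call(self, params):
        el = build_reference_element(FamilySpec("f", "MARINER", 1300, tir_len=25), seed=2)
        assert find_ltr_pair(el.record.seq, (0, 1300), params) is None

    def test_agrees_with_exhaustive_scan_on_small_elements(self, params):
        rng = random.Random(11)
        for trial in range(12):
            ltr = "TG" + _rand(rng, rng.randint(80, 140)) + "CA"
            internal = _rand(rng, rng.randint(300, 700))
            seq = ltr + internal + ltr
            call = find_ltr_pair(seq, (0, len(seq)), params)
            oracle = ltr_scan(seq, params.ltr_min_len, params.ltr_min_identity, params.boundary_jitter)
            assert call is not None and oracle is not None
            assert call.length == oracle[0]
            assert call.identity == pytest.approx(oracle[1], abs=0.01)


class TestFindTir:
    def test_constructed_palindromic_ends(self, params):
        seq = "CAGTTGCCA" + "G" * 60 + "TGGCAACTG"
        call = find_tir(seq, (0, len(seq)), params)
        # G-run interior extends the complementary stretch beyond the
        # planted 9-mer: verify against the enumeration oracle instead
        oracle = tir_scan(seq, params.tir_min_len, params.tir_max_mismatch)
        assert call is not None
        assert (call.length, call.mismatches) == oracle

    def test_ltr_element_has_no_tir(self, params):
        el = build_reference_element(FamilySpec("f", "LTR", 1200, ltr_len=90, tsd_len=5), seed=3)
        assert find_tir(el.record.seq, (0, 1200), params) is None

    def test_matches_bruteforce_over_terminal_lengths(self, params):
        rng = random.Random(13)
        for _ in range(30):
            tir = _rand(rng, rng.randint(10, 40))
            seq = tir + _rand(rng, rng.randint(50, 200)) + rc(tir)
            got = find_tir(seq, (0, len(seq)), params)
            exp = tir_scan(seq, params.tir_min_len, params.tir_max_mismatch)
            assert (got.length, got.mismatches) == exp


class TestFindPolya:
    def test_pure_a_suffix(self, params):
        call = find_polya("G" * 50 + "A" * 15, params)
        assert call is not None and call.tail_len >= 15

    def test_mixed_suffix_rejected(self, params):
        assert find_polya("G" * 50 + "ACGTACGTACGTACG", params) is None

    def test_tail_length_matches_suffix_scan(self, params):
        rng = random.Random(17)
        for _ in range(30):
            seq = _rand(rng, 60) + "".join(
                rng.choice("AAAG") for _ in range(rng.randint(10, 40))
            )
            got = find_polya(seq, params)
            exp = polya_scan(seq, params.polya_window, params.polya_min_frac)
            if exp is None:
                assert got is None
            else:
                assert got is not None and got.tail_len == exp


class TestClassifySuperfamily:
    def _feat(self, ttype, **detail):
        return StructuralFeatures(tsd=None, terminal_type=ttype, terminal_detail=detail)

    @pytest.mark.parametrize(
        "ttype,detail,tsd,expected",
        [
            ("TIR", {}, "TA", "Tc1/mariner"),
            ("LTR", {}, "ACGTA", "LTR_retrotransposon"),
            ("TIR", {"motif_cacta": True}, "ACG", "CACTA"),
            ("TIR", {}, "ACGTACGTA", "Mutator"),
            ("POLYA", {}, "ACGTACGTACGT", "LINE"),
            ("TIR", {}, "ACGTA", "UNCLASSIFIED"),
            ("NONE", {}, "AC", "UNCLASSIFIED"),
        ],
    )
    def test_rule_table(self, ttype, detail, tsd, expected):
        feat = StructuralFeatures(tsd=None, terminal_type=ttype, terminal_detail=detail)
        assert classify_superfamily(feat, tsd) == expected


class TestDefineElement:
    def _loci_for_family(self, genome, truth, family, params, query_len=None):
        """Anchor the family reference against the genome as a transcript
        would, then cut loci."""
        fam = truth.families[family]
        q = SequenceRecord("tx", fam.record.seq)
        hits = filter_significant(search_dna_vs_dna(q, genome, params), params)
        return [extract_locus(genome, h, params) for h in hits[:10]]

    def test_multicopy_mariner_recovered_exactly(self, params):
        specs = [FamilySpec("mar", "MARINER", 1300, tir_len=26, copy_number=3,
                            divergence=0.0, fragmentation_rate=0.0)]
        genome, truth = simulate_genome({"chr1": 120_000}, specs, seed=23)
        loci = self._loci_for_family(genome, truth, "mar", params)
        el = define_element(loci, "mar", params)
        assert el is not None
        assert el.features.tsd.seq == "TA"
        assert el.features.terminal_type == "TIR"
        assert el.superfamily == "Tc1/mariner"
        planted = {(iv.start, iv.end) for iv in truth.coords["ref"].values()}
        assert (el.location.start, el.location.end) in planted

    def test_single_fragmental_copy_yields_nothing(self, params):
        specs = [FamilySpec("mut", "MUTATOR", 2500, tir_len=60, tsd_len=9,
                            copy_number=1, divergence=0.0, fragmentation_rate=1.0)]
        genome, truth = simulate_genome({"chr1": 80_000}, specs, seed=29)
        ins = truth.insertions[0]
        assert not ins.intact
        iv = truth.coords["ref"][ins.insertion_id]
        hit = _mk_hit("chr1", iv.start, iv.end)
        loci = [extract_locus(genome, hit, params)]
        assert define_element(loci, "mut", params) is None

    def test_single_copy_ltr_element_recovered(self, params):
        specs = [FamilySpec("gyp", "LTR", 4000, ltr_len=150, tsd_len=5,
                            copy_number=1, divergence=0.0, fragmentation_rate=0.0)]
        genome, truth = simulate_genome({"chr1": 80_000}, specs, seed=31)
        iv = next(iter(truth.coords["ref"].values()))
        loci = [extract_locus(genome, _mk_hit("chr1", iv.start, iv.end), params)]
        el = define_element(loci, "gyp", params)
        assert el is not None
        assert el.superfamily == "LTR_retrotransposon"
        assert (el.location.start, el.location.end) == (iv.start, iv.end)

    def test_deterministic(self, params):
        specs = [FamilySpec("cac", "CACTA", 2000, tir_len=20, tsd_len=3,
                            copy_number=2, divergence=0.0, fragmentation_rate=0.0)]
        genome, truth = simulate_genome({"chr1": 100_000}, specs, seed=37)
        loci = self._loci_for_family(genome, truth, "cac", params)
        e1 = define_element(loci, "cac", params)
        e2 = define_element(loci, "cac", params)
        assert e1.location == e2.location and e1.element_seq == e2.element_seq
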