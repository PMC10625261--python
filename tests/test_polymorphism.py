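import itertools
import random

import pytest

from tetrack.core import Interval, SequenceRecord
from tetrack.align import SubjectIndex
from tetrack.boundaries import IntactElement, StructuralFeatures
from tetrack.polymorphism import (
    CATEGORIES,
    FlankMapping,
    classify_element,
    classify_orthology,
    make_flank_probe,
    map_flanks,
    summarize_comparison,
    OrthologyCall,
)
from tetrack.simulate import FamilySpec, derive_accession, simulate_genome


def _element(truth, genome, insertion_id, name=None):
    ins = truth.insertion(insertion_id)
    iv = truth.coords["ref"][insertion_id]
    seqs = {r.id: r.seq for r in genome}
    feats = StructuralFeatures(tsd=None, terminal_type="TIR")
    return IntactElement(
        name or insertion_id, ins.family, iv, "X", feats, seqs[iv.chrom][iv.start : iv.end]
    )


@pytest.fixture(scope="module")
def mariner_sim(params):
    specs = [FamilySpec("mar", "MARINER", 1300, tir_len=26, copy_number=5,
                        divergence=0.0, fragmentation_rate=0.0)]
    genome, truth = simulate_genome({"chr1": 200_000}, specs, seed=53)
    return genome, truth


class TestFlankProbe:
    def test_probe_arithmetic(self, mariner_sim, params):
        genome, truth = mariner_sim
        iid = truth.insertions[0].insertion_id
        el = _element(truth, genome, iid)
        probe = make_flank_probe(genome, el, params)
        iv = truth.coords["ref"][iid]
        seq = genome[0].seq
        assert probe.left_flank == seq[iv.start - 350 : iv.start]
        assert probe.right_flank == seq[iv.end : iv.end + 350]
        assert len(probe.probe) == 700
        assert not probe.clipped

    def test_clipping_flagged(self, params):
        rng = random.Random(3)
        chrom = SequenceRecord("c", "".join(rng.choice("ACGT") for _ in range(2000)))
        el = IntactElement(
            "e", "f", Interval("c", 100, 700), "X",
            StructuralFeatures(tsd=None, terminal_type="TIR"), chrom.seq[100:700],
        )
        probe = make_flank_probe([chrom], el, params)
        assert probe.clipped and len(probe.left_flank) == 100

    def test_whole_chromosome_element_errors(self, params):
        rng = random.Random(4)
        chrom = SequenceRecord("c", "".join(rng.choice("ACGT") for _ in range(900)))
        el = IntactElement(
            "e", "f", Interval("c", 0, 900), "X",
            StructuralFeatures(tsd=None, terminal_type="TIR"), chrom.seq,
        )
        with pytest.raises(ValueError):
            make_flank_probe([chrom], el, params)


class TestMapFlanks:
    def test_unique_exact_match(self, mariner_sim, params):
        genome, truth = mariner_sim
        el = _element(truth, genome, truth.insertions[0].insertion_id)
        probe = make_flank_probe(genome, el, params)
        left, right = map_flanks(probe, genome, params)
        assert left.label == right.label == "UNIQUE"

    def test_duplicated_flank_maps_multi(self, params):
        specs = [FamilySpec("mar", "MARINER", 1300, tir_len=26, copy_number=4,
                            divergence=0.0, fragmentation_rate=0.0)]
        genome, truth = simulate_genome(
            {"chr1": 200_000}, specs, seed=59, n_duplicated_flanks=2
        )
        assert truth.duplicated_flank_ids
        iid = truth.duplicated_flank_ids[0]
        el = _element(truth, genome, iid)
        probe = make_flank_probe(genome, el, params)
        left, right = map_flanks(probe, genome, params)
        assert left.label == "MULTI"
        assert right.label == "UNIQUE"

    def test_unrelated_genome_maps_none(self, mariner_sim, params):
        genome, truth = mariner_sim
        el = _element(truth, genome, truth.insertions[0].insertion_id)
        probe = make_flank_probe(genome, el, params)
        rng = random.Random(5)
        other = [SequenceRecord("x", "".join(rng.choice("ACGT") for _ in range(50_000)))]
        left, right = map_flanks(probe, other, params)
        assert left.label == right.label == "NONE"


class TestClassifyOrthology:
    def test_self_comparison_is_shared(self, mariner_sim, params):
        genome, truth = mariner_sim
        index = SubjectIndex(genome, params.word_size)
        for ins in truth.insertions:
            el = _element(truth, genome, ins.insertion_id)
            call = classify_element(genome, el, index, "self", params)
            assert call.category == "A_SHARED", (ins.insertion_id, call.reason)

    def test_planted_absences_called_absent(self, mariner_sim, params):
        genome, truth = mariner_sim
        acc = derive_accession(truth, 0.4, seed=61, genome_id="accP")
        index = SubjectIndex(acc, params.word_size)
        for ins in truth.insertions:
            el = _element(truth, genome, ins.insertion_id)
            call = classify_element(genome, el, index, "accP", params)
            expected = "A_SHARED" if truth.presence["accP"][ins.insertion_id] else "B_ABSENT"
            assert call.category == expected, (ins.insertion_id, call.reason)

    def test_deleted_locus_is_missing_both(self, mariner_sim, params):
        genome, truth = mariner_sim
        ins = truth.insertions[0]
        iv = truth.coords["ref"][ins.insertion_id]
        seq = genome[0].seq
        deleted = seq[: iv.start - 2000] + seq[iv.end + 2000 :]
        target = [SequenceRecord("chr1", deleted)]
        el = _element(truth, genome, ins.insertion_id)
        call = classify_element(genome, el, target, "del", params)
        assert call.category == "F_MISSING_BOTH"

    def test_every_label_combination_yields_exactly_one_category(self, mariner_sim, params):
        """The A-F categories are exhaustive and mutually exclusive over
        all flank-label combinations."""
        genome, truth = mariner_sim
        el = _element(truth, genome, truth.insertions[0].insertion_id)
        probe = make_flank_probe(genome, el, params)
        real_left, real_right = map_flanks(probe, genome, params)
        by_label = {"UNIQUE": real_left, "NONE": FlankMapping("NONE", [])}
        by_label["MULTI"] = FlankMapping("MULTI", real_left.hits * 2)
        for ll, rl in itertools.product(["UNIQUE", "MULTI", "NONE"], repeat=2):
            left = by_label[ll]
            right = by_label[rl] if rl != "UNIQUE" else real_right
            call = classify_orthology(left, right, el, genome, "t", params)
            assert call.category in CATEGORIES
            if ll == rl == "NONE":
                assert call.category == "F_MISSING_BOTH"
            elif "NONE" in (ll, rl):
                assert call.category == "E_MISSING_ONE"
            elif ll == rl == "MULTI":
                assert call.category == "C_MULTI_BOTH"
            elif "MULTI" in (ll, rl):
                assert call.category == "D_MULTI_ONE"


class TestSummaries:
    def _call(self, i, fam, cat):
        return OrthologyCall(element_id=f"e{i}", family=fam, target_genome_id="t", category=cat)

    def test_partition_sums(self):
        calls = [self._call(i, "famA", "A_SHARED") for i in range(8)]
        calls += [self._call(8 + i, "famB", "B_ABSENT") for i in range(2)]
        table = summarize_comparison(calls)
        total_row = table[table["family"] == "all"].iloc[0]
        assert total_row["total"] == 10
        assert total_row["A_SHARED"] == 8 and total_row["B_ABSENT"] == 2

    def test_empty_input(self):
        assert summarize_comparison([]).empty

    def test_categories_partition_probed_set_fuzz(self):
        rng = random.Random(67)
        for _ in range(20):
            calls = [
                self._call(i, rng.choice(["f1", "f2", "f3"]), rng.choice(CATEGORIES))
                for i in range(rng.randrange(1, 40))
            ]
            table = summarize_comparison(calls)
            allrow = table[table["family"] == "all"].iloc[0]
            assert sum(allrow[c] for c in CATEGORIES) == allrow["total"] == len(calls)
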